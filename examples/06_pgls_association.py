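"""Phylogenetic GLS: does selfing status predict an SNV metric?

Simulates a 20-species birth-death tree with a metric evolving as Brownian
motion plus a built-in selfing effect of -1, then fits the metric on the
selfing indicator with the error covariance proportional to shared branch
lengths.  Compares against an ordinary (phylogeny-blind) regression.
"""

import numpy as np

from selfsig import PGLSScenario, fit_all_metrics, make_pgls_dataset
from selfsig.pgls import brownian_covariance, pgls_fit

tree, traits = make_pgls_dataset(PGLSScenario(effect=-1.0, n_species=20), seed=3)
print(traits.head())

res = fit_all_metrics(traits, tree)
print("\nPGLS fit (Brownian covariance):")
print(res.round(4))

# phylogeny-blind OLS for comparison
X = np.column_stack([np.ones(len(traits)), traits["selfing"].to_numpy(float)])
ols = pgls_fit(traits["metric"].to_numpy(float), X, np.eye(len(traits)),
               names=["intercept", "selfing"])
print("\nOLS (ignoring the tree) selfing coefficient:",
      round(ols.params.loc['selfing', 'coef'], 4),
      "p =", f"{ols.params.loc['selfing', 'p']:.3g}")

# The PGLS coefficient recovers the simulated effect near -1; OLS gives a
# similar point estimate here but mis-states its uncertainty because related
# species are not independent samples.
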