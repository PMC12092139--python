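"""Phylogenetic generalized least squares under Brownian motion.

Regresses species-level trait means (e.g. heterozygous-SNV metrics) on a
selfing-status indicator while modelling the error covariance as Brownian
motion along a phylogeny: ``Cov(e_i, e_j) = sigma^2 * C_ij`` where ``C_ij``
is the shared root-to-MRCA path length of tips i and j.  Estimation uses the
GLS normal equations solved through a Cholesky factorization of ``C``
(whitening), never an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "PGLSFit",
    "brownian_covariance",
    "pgls_fit",
    "fit_all_metrics",
]

#: Reject covariance matrices with a 2-norm condition number above this.
CONDITION_LIMIT = 1e12


@dataclass
class PGLSFit:
    """GLS fit summary: one row per coefficient plus residual variance."""

    params: pd.DataFrame  # columns: coef, se, t, p
    sigma2: float
    df_resid: int

    def coef(self, name: str) -> float:
        return float(self.params.loc[name, "coef"])


def brownian_covariance(
    tree: dendropy.Tree, labels: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance matrix of the tree's tips.

    ``C[i, j]`` is the path length from the root to the most recent common
    ancestor of tips i and j (so ``C[i, i]`` is the root-to-tip depth).  The
    tree is used as given; it need not be ultrametric.  Edges without a
    length contribute 0 except that a fully zero-depth tree is rejected.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    depth_maps = {}
    for leaf in leaves:
        path = {}
        depth = 0.0
        node = leaf
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        # chain is leaf..root; accumulate depth root-down.
        depth = 0.0
        for node in reversed(chain):
            if node.parent_node is not None:
                depth += node.edge.length or 0.0
            path[id(node)] = depth
        depth_maps[leaf.taxon.label] = path
    names = [lf.taxon.label for lf in leaves]
    if labels is not None:
        missing = set(labels) - set(names)
        if missing:
            raise KeyError(f"tips absent from tree: {sorted(missing)}")
        names = list(labels)
    n = len(names)
    C = np.zeros((n, n))
    for i in range(n):
        pi = depth_maps[names[i]]
        for j in range(i, n):
            pj = depth_maps[names[j]]
            shared = [d for node_id, d in pi.items() if node_id in pj]
            C[i, j] = C[j, i] = max(shared)
    if np.all(C == 0):
        raise ValueError("tree has zero total depth; covariance is singular")
    return names, C


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    names: list[str] | None = None,
) -> PGLSFit:
    """GLS estimate ``beta = (X' C^-1 X)^-1 X' C^-1 y`` with t-tests.

    ``X`` must include its intercept column.  ``C`` must be symmetric
    positive definite; the fit whitens by the Cholesky factor of ``C`` and
    solves ordinary least squares on the whitened system.  Coefficient
    standard errors use the residual variance on ``n - p`` degrees of
    freedom; p-values are two-sided.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X disagree on n")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T):
        raise ValueError("C must be symmetric")
    if np.linalg.cond(C) > CONDITION_LIMIT:
        raise ValueError("C is numerically singular (condition number too large)")
    L = linalg.cholesky(C, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {np.linalg.matrix_rank(xtx)} < {p})"
        )
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    names = names if names is not None else [f"x{i}" for i in range(p)]
    params = pd.DataFrame(
        {"coef": beta, "se": se, "t": tvals, "p": pvals}, index=names
    )
    return PGLSFit(params=params, sigma2=sigma2, df_resid=df)


def fit_all_metrics(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    selfing_col: str = "selfing",
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Fit each metric against the selfing indicator under Brownian PGLS.

    ``traits`` is indexed by species (matching tree tip labels) with a
    binary ``selfing`` column and numeric metric columns.  One independent
    fit per metric; no multiple-testing correction is applied, which is
    flagged in the output frame's ``note`` attribute.
    """
    metrics = metrics or [
        c for c in traits.columns if c != selfing_col and pd.api.types.is_numeric_dtype(traits[c])
    ]
    if not metrics:
        raise ValueError("no numeric metric columns found")
    species = list(traits.index)
    _, C = brownian_covariance(tree, labels=species)
    x = traits[selfing_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(species)), x])
    rows = []
    for metric in metrics:
        fit = pgls_fit(
            traits[metric].to_numpy(dtype=float),
            X,
            C,
            names=["intercept", selfing_col],
        )
        r = fit.params.loc[selfing_col]
        rows.append(
            (metric, r["coef"], r["se"], r["t"], r["p"], float(np.sign(r["coef"])))
        )
    out = pd.DataFrame(
        rows, columns=["metric", "coef_selfing", "se", "t", "p", "sign"]
    ).set_index("metric")
    out.attrs["note"] = "p-values are per-metric; no multiple-testing correction"
    return out
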