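"""SSR diversity statistics and a D_A neighbour-joining tree on synthetic
sister-pair data.

Generates the default scenario (a partially selfing chasmogamous population
plus a cleistogamous lineage founded from it ten generations ago), then
computes per-species allele counts, rarefaction allelic richness, observed
and expected heterozygosity, and builds a neighbour-joining tree on Nei's
D_A distance between individual multilocus genotypes with locus-resampling
bootstrap support at the population level.
"""

import numpy as np

from selfsig import (
    allelic_richness,
    bootstrap_support,
    locus_diversity,
    make_sister_pair_ssr,
)

table = make_sister_pair_ssr(seed=42)

print("species        mean_A  mean_R_S  mean_H_O  mean_H_E")
for sp in ("chasmogamous", "cleistogamous"):
    div = locus_diversity(table, sp)
    rs = allelic_richness(table, sp, g=20)
    print(
        f"{sp:14s} {div['A'].mean():6.2f} {rs.mean():9.3f}"
        f" {div['H_O'].mean():9.4f} {div['H_E'].mean():9.4f}"
    )

cle = table.subset(table.species == "cleistogamous")
flat = cle.alleles.reshape(cle.n_samples, -1)
print(f"\ncleistogamous samples sharing one multilocus genotype: "
      f"{int((flat == flat[0]).all(axis=1).sum())}/{cle.n_samples}")

# Genotype-level tree on a subsample (NJ needs >= 3 taxa; individual-level
# D_A treats each sample's multilocus genotype as a frequency vector).
sub = table.subset(np.r_[0:5, 54:57])
tree, support = bootstrap_support(sub, n_reps=200, seed=1, by="individual")
print("\nNJ tree (genotype-level D_A, 8 samples):", tree.newick())
for bp, frac in sorted(support.items(), key=lambda kv: -kv[1])[:3]:
    print(f"  bipartition {sorted(bp)}: {100 * frac:.0f}% bootstrap support")

# The selfing lineage shows a single shared genotype and zero observed
# heterozygosity, the uniformity signature the clock converts into an age.
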