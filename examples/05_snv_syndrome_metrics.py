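"""Heterozygous-SNV selfing-syndrome metrics and a sister-pair contrast.

Generates per-sample transcript variant tables for a selfing-profile
species (sparse heterozygous SNVs, enriched for nonsynonymous and
deleterious variants) and an outcrossing-profile species, computes the
per-sample metrics, and contrasts them with Student's t-test.  A variant is
deleterious when |score| > 2.5 (the absolute value because ancestral and
derived states are indistinguishable at heterozygous sites).
"""

import pandas as pd

from selfsig import VariantScenario, make_variant_tables, metrics_frame, species_means
from selfsig.snv_metrics import compare_pair_frame

selfer = make_variant_tables(
    VariantScenario(species="selfer", snv_per_kb=0.15, nonsyn_fraction=0.5,
                    deleterious_fraction=0.4),
    seed=1,
)
outcrosser = make_variant_tables(
    VariantScenario(species="outcrosser", snv_per_kb=1.2, nonsyn_fraction=0.35,
                    deleterious_fraction=0.2),
    seed=2,
)

frame = pd.concat([metrics_frame(selfer), metrics_frame(outcrosser)])
print("species means:")
print(species_means(frame).round(4))

print("\nStudent t-test, selfer vs outcrosser:")
print(compare_pair_frame(frame, "selfer", "outcrosser").round(4))

# Negative t for SNVs/kb (selfers carry less heterozygous variation) and
# positive t for the nonsynonymous and deleterious fractions (what variation
# remains is enriched for damaging changes) is the genomic selfing syndrome.
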