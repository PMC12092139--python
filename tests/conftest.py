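import numpy as np
import pandas as pd
import pytest

from selfsig.popgen_ssr import SSRGenotypeTable
from selfsig.snp_pipeline import SNPMatrix
from selfsig.snv_metrics import COLUMNS, VariantTable


@pytest.fixture
def hand_ssr_table() -> SSRGenotypeTable:
    """Four individuals, two loci, two populations; hand-checkable counts."""
    alleles = np.array(
        [
            [[100, 100], [200, 202]],
            [[100, 102], [200, 202]],
            [[102, 102], [200, 202]],
            [[100, 102], [200, 200]],
        ]
    )
    return SSRGenotypeTable(
        samples=["a", "b", "c", "d"],
        population=np.array(["p1", "p1", "p2", "p2"], dtype=object),
        species=np.array(["x", "x", "x", "x"], dtype=object),
        loci=["L1", "L2"],
        alleles=alleles,
    )


@pytest.fixture
def toy_snp_matrix() -> SNPMatrix:
    """Ten samples, five SNPs on three locus groups, engineered so each
    filtering rule has exactly one obvious casualty.

    snp_het: heterozygous in 7/10 samples (H_O = 0.7 >= 0.6).
    snp_keep: minor allele carried by exactly 3 samples.
    snp_rare: minor allele carried by 2 samples only.
    snp_miss: genotyped in 5/10 samples (R = 0.5).
    snp_second: second SNP on the same locus group as snp_keep.
    """
    g = np.array(
        [
            # het keep rare miss second
            [1, 1, 0, -1, 0],
            [1, 1, 0, -1, 0],
            [1, 1, 0, -1, 0],
            [1, 0, 0, -1, 2],
            [1, 0, 0, -1, 2],
            [1, 0, 2, 0, 2],
            [1, 0, 2, 0, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 1, 0],
            [2, 0, 0, 2, 0],
        ],
        dtype=np.int8,
    )
    labels = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
    return SNPMatrix(
        samples=[f"s{i}" for i in range(10)],
        species=labels,
        population=labels.copy(),
        snp_ids=["snp_het", "snp_keep", "snp_rare", "snp_miss", "snp_second"],
        locus_ids=np.array(["loc1", "loc2", "loc3", "loc1", "loc2"], dtype=object),
        pos_in_locus=np.array([1, 1, 1, 2, 2]),
        genotypes=g,
    )


@pytest.fixture
def hand_variant_table() -> VariantTable:
    """One sample, two transcripts totalling 2 kb, four SNVs: two synonymous
    and two nonsynonymous with scores -3.1 (deleterious) and -1.0 (neutral)."""
    rows = [
        ("s1", "sp", "t1", 1000, "v1", "synonymous", np.nan),
        ("s1", "sp", "t1", 1000, "v2", "synonymous", np.nan),
        ("s1", "sp", "t1", 1000, "v3", "nonsynonymous", -3.1),
        ("s1", "sp", "t2", 1000, "v4", "nonsynonymous", -1.0),
    ]
    return VariantTable(pd.DataFrame(rows, columns=COLUMNS))
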