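"""Heterozygous-SNV "genomic selfing syndrome" metrics.

Consumes per-sample variant tables (one row per heterozygous SNV plus one
row per SNV-free transcript) carrying transcript lengths, effect classes
(synonymous / nonsynonymous) and precomputed deleteriousness scores, and
produces the per-sample metrics used to profile mating systems from
transcriptome data: SNVs per kb, nonsynonymous and deleterious fractions,
deleterious SNVs per kb, and the fraction of transcripts carrying a
nonsynonymous SNV.  Sister-species contrasts use a two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantTable",
    "SyndromeMetrics",
    "DELETERIOUS_THRESHOLD",
    "classify_deleterious",
    "syndrome_metrics",
    "metrics_frame",
    "compare_species_pair",
    "species_means",
]

#: Absolute deleteriousness-score cutoff: a nonsynonymous variant is called
#: deleterious when |score| strictly exceeds this value (the absolute value
#: because ancestral and derived states cannot be told apart at
#: heterozygous sites).
DELETERIOUS_THRESHOLD = 2.5

COLUMNS = ["sample", "species", "transcript_id", "transcript_len_bp", "snv_id", "effect", "score"]
METRIC_NAMES = [
    "snv_per_kb",
    "nonsyn_fraction",
    "deleterious_fraction",
    "deleterious_per_kb",
    "fraction_transcripts_with_nonsyn_snv",
]


@dataclass
class VariantTable:
    """Per-sample heterozygous SNVs over a transcript set.

    ``df`` columns: sample, species, transcript_id, transcript_len_bp,
    snv_id, effect ('synonymous' | 'nonsynonymous' | NA for a transcript row
    with no SNVs), score (float, NA unless nonsynonymous).  Every analysed
    transcript appears at least once so the length denominator is complete.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if (self.df["transcript_len_bp"] <= 0).any():
            raise ValueError("transcript lengths must be positive")
        eff = self.df["effect"].dropna()
        bad = set(eff.unique()) - {"synonymous", "nonsynonymous"}
        if bad:
            raise ValueError(f"unknown effect classes: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.df["sample"]))

    def for_sample(self, sample: str) -> pd.DataFrame:
        sub = self.df[self.df["sample"] == sample]
        if sub.empty:
            raise KeyError(f"no rows for sample {sample!r}")
        return sub


@dataclass
class SyndromeMetrics:
    """Per-sample selfing-syndrome summary.

    ``n_unclassified`` counts nonsynonymous SNVs lacking a score; they stay
    in SNV totals but are excluded from the deleterious-fraction numerator
    and flagged here rather than silently dropped.
    """

    snv_per_kb: float
    nonsyn_fraction: float
    deleterious_fraction: float
    deleterious_per_kb: float
    fraction_transcripts_with_nonsyn_snv: float
    n_snvs: int
    n_unclassified: int

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in METRIC_NAMES})


def classify_deleterious(
    score: float, threshold: float = DELETERIOUS_THRESHOLD, strict: bool = True
) -> bool:
    """True when ``|score|`` exceeds the threshold (strictly by default;
    ``strict=False`` includes the boundary)."""
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    a = abs(score)
    return a > threshold if strict else a >= threshold


def syndrome_metrics(
    v: VariantTable | pd.DataFrame,
    sample: str | None = None,
    threshold: float = DELETERIOUS_THRESHOLD,
    strict: bool = True,
) -> SyndromeMetrics:
    """Compute the syndrome metrics for one sample's variant rows.

    SNV rows are rows with a non-null effect.  Fractions are over all SNVs;
    the deleterious fraction's denominator excludes nonsynonymous SNVs with
    missing scores (reported via ``n_unclassified``).
    """
    df = v.df if isinstance(v, VariantTable) else v
    if sample is not None:
        df = df[df["sample"] == sample]
    if df.empty:
        raise ValueError("empty variant table")
    lengths = df.drop_duplicates("transcript_id").set_index("transcript_id")[
        "transcript_len_bp"
    ]
    total_kb = float(lengths.sum()) / 1000.0
    if total_kb <= 0:
        raise ValueError("total transcript length must be positive")
    snvs = df[df["effect"].notna()]
    n_snvs = len(snvs)
    nonsyn = snvs[snvs["effect"] == "nonsynonymous"]
    unclassified = nonsyn["score"].isna()
    n_uncls = int(unclassified.sum())
    scored = nonsyn.loc[~unclassified, "score"].to_numpy(dtype=float)
    n_del = int(
        sum(classify_deleterious(s, threshold=threshold, strict=strict) for s in scored)
    )
    n_classifiable = n_snvs - n_uncls
    transcripts_nonsyn = nonsyn["transcript_id"].nunique()
    return SyndromeMetrics(
        snv_per_kb=n_snvs / total_kb,
        nonsyn_fraction=len(nonsyn) / n_snvs if n_snvs else 0.0,
        deleterious_fraction=n_del / n_classifiable if n_classifiable else 0.0,
        deleterious_per_kb=n_del / total_kb,
        fraction_transcripts_with_nonsyn_snv=transcripts_nonsyn / lengths.size,
        n_snvs=n_snvs,
        n_unclassified=n_uncls,
    )


def metrics_frame(
    v: VariantTable, threshold: float = DELETERIOUS_THRESHOLD, strict: bool = True
) -> pd.DataFrame:
    """Per-sample metrics table (rows: samples; includes species labels)."""
    rows = {}
    species = {}
    for s in v.samples:
        sub = v.for_sample(s)
        rows[s] = syndrome_metrics(sub, threshold=threshold, strict=strict).as_series()
        species[s] = sub["species"].iloc[0]
    out = pd.DataFrame(rows).T
    out.insert(0, "species", pd.Series(species))
    out.index.name = "sample"
    return out


def compare_species_pair(
    metrics_a: np.ndarray | list[float],
    metrics_b: np.ndarray | list[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test (Student equal-variance by default, Welch optional)
    on per-sample metric values; returns (t, two-sided p).

    The degenerate case of zero variance in both groups with equal means is
    reported as (0.0, 1.0).
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per species")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    import warnings

    with warnings.catch_warnings():
        # zero variance within one group is legitimate for fraction metrics
        warnings.filterwarnings("ignore", message=".*catastrophic cancellation.*")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_pair_frame(
    frame: pd.DataFrame, species_a: str, species_b: str, welch: bool = False
) -> pd.DataFrame:
    """t-test each syndrome metric between two species in a metrics frame."""
    fa = frame[frame["species"] == species_a]
    fb = frame[frame["species"] == species_b]
    rows = []
    for metric in METRIC_NAMES:
        t, p = compare_species_pair(fa[metric], fb[metric], welch=welch)
        rows.append((metric, t, p))
    return pd.DataFrame(rows, columns=["metric", "t", "p"]).set_index("metric")


def species_means(frame: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each metric per species (PGLS trait-table rows)."""
    return frame.groupby("species")[METRIC_NAMES].mean()
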