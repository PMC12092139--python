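"""SNP-matrix filtering, polarization and divergence summaries.

Works on biallelic SNP genotype matrices (codes 0/1/2 = hom-ref / het /
hom-alt, -1 = missing) grouped by the physical locus of origin, as produced
by reduced-representation genotyping.  Implements the filtering cascade used
to clean such data (excess-heterozygosity removal, minor-allele sample
count, per-SNP missingness, one-SNP-per-locus thinning), allele polarization
against the allele predominant in a designated ancestral group, fixed-
difference counts, per-site nucleotide diversity and the Evanno ΔK statistic
for choosing the number of genetic clusters from clustering log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SNPMatrix",
    "FilterReport",
    "filter_snps",
    "observed_het_per_snp",
    "polarize_and_histogram",
    "count_fixed_differences",
    "nucleotide_diversity",
    "snp_diversity",
    "evanno_delta_k",
]

MISSING = -1


@dataclass
class SNPMatrix:
    """Biallelic SNP genotypes with per-SNP locus grouping.

    ``genotypes`` has shape (n_samples, n_snps), int8 codes 0/1/2 and -1 for
    missing.  ``locus_ids`` maps each SNP to its physical locus of origin;
    ``pos_in_locus`` orders SNPs within a locus.
    """

    samples: list[str]
    species: np.ndarray
    population: np.ndarray
    snp_ids: list[str]
    locus_ids: np.ndarray
    pos_in_locus: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        n, s = len(self.samples), len(self.snp_ids)
        self.species = np.asarray(self.species, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.pos_in_locus = np.asarray(self.pos_in_locus, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (n, s):
            raise ValueError(
                f"genotypes must have shape {(n, s)}, got {self.genotypes.shape}"
            )
        if len(self.locus_ids) != s or len(self.pos_in_locus) != s:
            raise ValueError("per-SNP annotations must match SNP count")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def take_snps(self, idx: np.ndarray) -> "SNPMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return SNPMatrix(
            samples=list(self.samples),
            species=self.species,
            population=self.population,
            snp_ids=[self.snp_ids[i] for i in idx],
            locus_ids=self.locus_ids[idx],
            pos_in_locus=self.pos_in_locus[idx],
            genotypes=self.genotypes[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "SNPMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return SNPMatrix(
            samples=[self.samples[i] for i in idx],
            species=self.species[idx],
            population=self.population[idx],
            snp_ids=list(self.snp_ids),
            locus_ids=self.locus_ids,
            pos_in_locus=self.pos_in_locus,
            genotypes=self.genotypes[idx, :],
        )

    def group_mask(self, label: str) -> np.ndarray:
        mask = (self.species == label) | (self.population == label)
        if not mask.any():
            raise KeyError(f"no samples labelled {label!r}")
        return mask


@dataclass
class FilterReport:
    """Per-rule removal counts for a filtering pass."""

    n_input: int
    removed_high_het: int = 0
    removed_minor_count: int = 0
    removed_missingness: int = 0
    removed_linked: int = 0
    n_surviving: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.removed_high_het
            + self.removed_minor_count
            + self.removed_missingness
            + self.removed_linked
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "removed_high_het": self.removed_high_het,
            "removed_minor_count": self.removed_minor_count,
            "removed_missingness": self.removed_missingness,
            "removed_linked": self.removed_linked,
            "n_surviving": self.n_surviving,
        }


def observed_het_per_snp(m: SNPMatrix) -> np.ndarray:
    """Fraction of genotyped samples that are heterozygous, per SNP."""
    g = m.genotypes
    called = g != MISSING
    with np.errstate(invalid="ignore"):
        return np.where(
            called.sum(axis=0) > 0,
            (g == 1).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
            np.nan,
        )


def _minor_allele_sample_counts(g: np.ndarray) -> np.ndarray:
    """Number of samples carrying the minor allele (het or hom), per SNP.

    The minor allele is the less frequent of the two by allele-copy count
    over genotyped samples; on an exact 50/50 tie the alternate allele is
    treated as minor.
    """
    called = g != MISSING
    alt_copies = np.where(called, np.maximum(g, 0), 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    minor_is_alt = alt_copies * 2 <= total
    carries_alt = ((g == 1) | (g == 2)).sum(axis=0)
    carries_ref = ((g == 1) | (g == 0)).sum(axis=0)
    return np.where(minor_is_alt, carries_alt, carries_ref)


def filter_snps(
    m: SNPMatrix,
    max_ho: float = 0.6,
    min_minor_samples: int = 3,
    min_prop_r: float = 0.0,
    one_per_locus: bool = False,
) -> tuple[SNPMatrix, FilterReport]:
    """Apply the SNP filtering cascade and report per-rule removals.

    In order: (1) drop SNPs with observed heterozygosity >= ``max_ho``
    (excess heterozygosity flags collapsed paralogs); (2) drop SNPs whose
    minor allele is carried by fewer than ``min_minor_samples`` samples;
    (3) drop SNPs genotyped in less than ``min_prop_r`` of samples; (4) if
    ``one_per_locus``, keep only the first SNP per locus group by
    within-locus position, discarding linked SNPs.
    """
    if m.n_snps == 0:
        raise ValueError("empty SNP matrix")
    if not (0.0 <= max_ho <= 1.0 and 0.0 <= min_prop_r <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    report = FilterReport(n_input=m.n_snps)

    ho = observed_het_per_snp(m)
    keep = ~(ho >= max_ho)  # NaN (no calls) survives this rule
    report.removed_high_het = int((~keep).sum())
    m = m.take_snps(keep)

    minor = _minor_allele_sample_counts(m.genotypes)
    keep = minor >= min_minor_samples
    report.removed_minor_count = int((~keep).sum())
    m = m.take_snps(keep)

    called_prop = (m.genotypes != MISSING).mean(axis=0)
    keep = called_prop >= min_prop_r
    report.removed_missingness = int((~keep).sum())
    m = m.take_snps(keep)

    if one_per_locus and m.n_snps:
        first = {}
        for i, (loc, pos) in enumerate(zip(m.locus_ids, m.pos_in_locus)):
            if loc not in first or pos < m.pos_in_locus[first[loc]]:
                first[loc] = i
        keep_idx = np.zeros(m.n_snps, dtype=bool)
        keep_idx[list(first.values())] = True
        report.removed_linked = int((~keep_idx).sum())
        m = m.take_snps(keep_idx)

    report.n_surviving = m.n_snps
    assert report.total_removed + report.n_surviving == report.n_input
    return m, report


def _group_allele_freq(g: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per SNP over genotyped samples; NaN if none."""
    called = g != MISSING
    copies = 2 * called.sum(axis=0)
    alt = np.where(called, np.maximum(g, 0), 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)


def polarize_and_histogram(
    m: SNPMatrix,
    ancestral_group: str,
    derived_group: str,
    bins: int = 10,
) -> dict:
    """Derived-allele frequency spectra with alleles polarized against the
    ancestral (chasmogamous) group.

    Per SNP the ancestral allele is the majority allele in
    ``ancestral_group``; a 50/50 tie resolves to the reference allele and is
    counted.  SNPs with no calls in the ancestral group are excluded and
    counted.  Returns per-group derived-allele frequencies, histograms on
    ``bins`` equal bins over [0, 1], and bookkeeping counts.
    """
    anc_mask = m.group_mask(ancestral_group)
    der_mask = m.group_mask(derived_group)
    f_anc_alt = _group_allele_freq(m.genotypes[anc_mask])
    usable = ~np.isnan(f_anc_alt)
    n_excluded = int((~usable).sum())
    # Ancestral allele: majority in the ancestral group; ties -> reference.
    anc_is_alt = f_anc_alt > 0.5
    n_ties = int((f_anc_alt == 0.5).sum())

    out_freqs = {}
    edges = np.linspace(0.0, 1.0, bins + 1)
    hists = {}
    for name, mask in ((ancestral_group, anc_mask), (derived_group, der_mask)):
        f_alt = _group_allele_freq(m.genotypes[mask])
        derived = np.where(anc_is_alt, 1.0 - f_alt, f_alt)
        derived = derived[usable]
        out_freqs[name] = derived
        hists[name], _ = np.histogram(derived[~np.isnan(derived)], bins=edges)
    return {
        "derived_freq": out_freqs,
        "histogram": hists,
        "bin_edges": edges,
        "n_excluded_no_ancestral_calls": n_excluded,
        "n_ties_resolved_to_ref": n_ties,
    }


def count_fixed_differences(m: SNPMatrix, group_a: str, group_b: str) -> int:
    """SNPs monomorphic for opposite alleles in the two groups (missing
    genotypes excluded; SNPs without calls in either group do not count)."""
    fa = _group_allele_freq(m.genotypes[m.group_mask(group_a)])
    fb = _group_allele_freq(m.genotypes[m.group_mask(group_b)])
    with np.errstate(invalid="ignore"):
        fixed = ((fa == 0.0) & (fb == 1.0)) | ((fa == 1.0) & (fb == 0.0))
    return int(np.nansum(fixed))


def nucleotide_diversity(m: SNPMatrix, group: str | None = None) -> pd.Series:
    """Per-SNP nucleotide diversity ``pi = (n/(n-1)) * 2 p (1-p)`` over the
    group's genotyped allele copies (the average pairwise difference)."""
    g = m.genotypes if group is None else m.genotypes[m.group_mask(group)]
    called = g != MISSING
    n = 2 * called.sum(axis=0)
    p = _group_allele_freq(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, n / np.maximum(n - 1, 1) * 2 * p * (1 - p), np.nan)
    return pd.Series(pi, index=m.snp_ids, name="pi")


def snp_diversity(m: SNPMatrix, group: str | None = None) -> pd.DataFrame:
    """Per-SNP H_O, H_E, F_IS and pi for a group, plus private-allele-ready
    allele frequency."""
    g = m.genotypes if group is None else m.genotypes[m.group_mask(group)]
    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, (g == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    p = _group_allele_freq(g)
    he = 2 * p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        fis = np.where(he > 0, (he - ho) / he, np.nan)
    pi = nucleotide_diversity(m, group).to_numpy()
    return pd.DataFrame(
        {"p_alt": p, "H_O": ho, "H_E": he, "F_IS": fis, "pi": pi}, index=m.snp_ids
    )


def evanno_delta_k(runs: dict[int, list[float]]) -> pd.Series:
    """Evanno ΔK from clustering log-likelihoods over independent runs.

    ``ΔK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))`` for each
    interior K of a consecutive K range; ``sd`` is the sample standard
    deviation (ddof=1) across runs at K.  K values where sd = 0 yield NaN.
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("ΔK needs >= 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K for a standard deviation")
    means = {k: float(np.mean(runs[k])) for k in ks}
    sds = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    out = {}
    for k in ks[1:-1]:
        second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
        out[k] = second / sds[k] if sds[k] > 0 else np.nan
    return pd.Series(out, name="delta_K")
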