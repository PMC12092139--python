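"""SSR summary statistics, Nei's D_A distance and neighbour-joining trees.

Operates on diploid multilocus SSR genotype tables (allele sizes, 0 =
missing).  Implements the classical descriptors used to characterise mating
systems from marker data — allele counts ``A``, rarefaction allelic richness
``R_S``, observed/expected heterozygosity ``H_O``/``H_E``, the inbreeding
coefficient ``F_IS``, private alleles — plus Nei's ``D_A`` genetic distance,
Saitou–Nei neighbour joining and locus-resampling bootstrap support.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import UnrootedTree

__all__ = [
    "SSRGenotypeTable",
    "DistanceMatrix",
    "allele_frequencies",
    "locus_diversity",
    "allelic_richness",
    "inbreeding_coefficient",
    "private_alleles",
    "nei_da",
    "da_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
]

MISSING = 0  # allele-size code for a failed amplification


@dataclass
class SSRGenotypeTable:
    """Diploid multilocus SSR genotypes with population/species labels.

    ``alleles`` has shape (n_samples, n_loci, 2) and holds integer allele
    sizes; 0 codes a missing allele copy.  Allele pairs are unordered.
    """

    samples: list[str]
    population: np.ndarray
    species: np.ndarray
    loci: list[str]
    alleles: np.ndarray
    motif_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, L = len(self.samples), len(self.loci)
        self.population = np.asarray(self.population, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles must have shape {(n, L, 2)}, got {self.alleles.shape}"
            )
        if len(self.population) != n or len(self.species) != n:
            raise ValueError("labels must match sample count")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, idx: np.ndarray) -> "SSRGenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return SSRGenotypeTable(
            samples=[self.samples[i] for i in idx],
            population=self.population[idx],
            species=self.species[idx],
            loci=list(self.loci),
            alleles=self.alleles[idx],
            motif_lengths=self.motif_lengths,
        )

    def complete_cases(self) -> "SSRGenotypeTable":
        """Drop samples with any missing allele copy (complete-case panel)."""
        ok = np.all(self.alleles != MISSING, axis=(1, 2))
        return self.subset(ok)

    def group_indices(self, by: str = "population") -> dict[str, np.ndarray]:
        labels = getattr(self, by)
        return {g: np.nonzero(labels == g)[0] for g in pd.unique(labels)}


def _resolve_group(table: SSRGenotypeTable, group) -> np.ndarray:
    """Group selector: None = all samples, a str matches population then
    species labels, otherwise an index/boolean array."""
    if group is None:
        return np.arange(table.n_samples)
    if isinstance(group, str):
        idx = np.nonzero(table.population == group)[0]
        if idx.size == 0:
            idx = np.nonzero(table.species == group)[0]
        if idx.size == 0:
            raise KeyError(f"no samples with population or species label {group!r}")
        return idx
    idx = np.asarray(group)
    if idx.dtype == bool:
        idx = np.nonzero(idx)[0]
    if idx.size == 0:
        raise ValueError("empty group")
    return idx


def allele_frequencies(
    table: SSRGenotypeTable, group=None
) -> dict[str, dict[int, float]]:
    """Per-locus allele frequencies over non-missing allele copies.

    Loci with no genotyped copies in the group map to an empty dict (flagged
    for downstream exclusion).
    """
    idx = _resolve_group(table, group)
    out: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(table.loci):
        copies = table.alleles[idx, j, :].ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            out[locus] = {}
            continue
        vals, counts = np.unique(copies, return_counts=True)
        out[locus] = {int(v): c / copies.size for v, c in zip(vals, counts)}
    return out


def locus_diversity(
    table: SSRGenotypeTable, group=None, unbiased: bool = False
) -> pd.DataFrame:
    """Per-locus allele count ``A``, observed and expected heterozygosity.

    ``H_O`` is the fraction of fully genotyped individuals that are
    heterozygous; ``H_E = 1 - sum(p_k^2)`` (Nei's gene diversity), with the
    small-sample ``2N/(2N-1)`` correction applied when ``unbiased=True``.
    """
    idx = _resolve_group(table, group)
    rows = []
    for j, locus in enumerate(table.loci):
        pairs = table.alleles[idx, j, :]
        full = np.all(pairs != MISSING, axis=1)
        copies = pairs.ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            rows.append((locus, np.nan, np.nan, np.nan))
            continue
        _, counts = np.unique(copies, return_counts=True)
        p = counts / copies.size
        he = 1.0 - float(np.sum(p**2))
        if unbiased and copies.size > 1:
            he *= copies.size / (copies.size - 1)
        ho = (
            float(np.mean(pairs[full, 0] != pairs[full, 1])) if full.any() else np.nan
        )
        rows.append((locus, len(counts), ho, he))
    df = pd.DataFrame(rows, columns=["locus", "A", "H_O", "H_E"]).set_index("locus")
    return df


def allelic_richness(
    table: SSRGenotypeTable, group=None, g: int | None = None
) -> pd.Series:
    """Rarefaction allelic richness ``R_S`` per locus at ``g`` gene copies.

    Hurlbert's estimator: ``R_S = sum_i [1 - C(N - N_i, g) / C(N, g)]`` with
    ``N`` genotyped copies and ``N_i`` copies of allele ``i``; the expected
    allele count in a random subsample of ``g`` copies.  ``g`` defaults to
    the smallest per-locus copy count in the group.
    """
    idx = _resolve_group(table, group)
    copy_counts = [
        int((table.alleles[idx, j, :] != MISSING).sum()) for j in range(table.n_loci)
    ]
    if min(copy_counts) == 0:
        raise ValueError("a locus has no genotyped copies in this group")
    if g is None:
        g = min(copy_counts)
    if g < 1:
        raise ValueError("g must be >= 1")
    out = {}
    for j, locus in enumerate(table.loci):
        copies = table.alleles[idx, j, :].ravel()
        copies = copies[copies != MISSING]
        n = copies.size
        if g > n:
            raise ValueError(f"g={g} exceeds {n} genotyped copies at {locus}")
        _, counts = np.unique(copies, return_counts=True)
        denom = math.comb(n, g)
        rs = sum(1.0 - math.comb(n - ni, g) / denom for ni in counts)
        out[locus] = rs
    return pd.Series(out, name=f"R_S(g={g})")


def inbreeding_coefficient(
    table: SSRGenotypeTable, group=None
) -> tuple[pd.Series, float]:
    """Per-locus ``F_IS = (H_E - H_O) / H_E`` and its mean over polymorphic
    loci; NaN when no locus is polymorphic."""
    div = locus_diversity(table, group)
    poly = div["H_E"] > 0
    fis = (div["H_E"] - div["H_O"]) / div["H_E"]
    fis[~poly] = np.nan
    mean = float(fis[poly].mean()) if poly.any() else float("nan")
    return fis.rename("F_IS"), mean


def private_alleles(table: SSRGenotypeTable, by: str = "population") -> dict[str, int]:
    """Count alleles observed in exactly one group, per group."""
    groups = table.group_indices(by)
    if len(groups) < 2:
        raise ValueError("private alleles need >= 2 groups")
    presence: dict[tuple[str, int], set[str]] = {}
    for gname, idx in groups.items():
        for j, locus in enumerate(table.loci):
            copies = table.alleles[idx, j, :].ravel()
            for a in np.unique(copies[copies != MISSING]):
                presence.setdefault((locus, int(a)), set()).add(gname)
    counts = {g: 0 for g in groups}
    for (_, _), owners in presence.items():
        if len(owners) == 1:
            counts[next(iter(owners))] += 1
    return counts


def nei_da(
    freqs_x: dict[str, dict[int, float]],
    freqs_y: dict[str, dict[int, float]],
) -> float:
    """Nei's ``D_A`` distance between two sets of per-locus allele frequencies.

    ``D_A = 1 - (1/L) * sum_loci sum_alleles sqrt(x_i * y_i)``.  Loci absent
    (no data) in either group are excluded and ``L`` adjusted, with a warning.
    """
    shared = [
        loc
        for loc in freqs_x
        if loc in freqs_y and freqs_x[loc] and freqs_y[loc]
    ]
    dropped = set(freqs_x) | set(freqs_y)
    dropped -= set(shared)
    if dropped:
        warnings.warn(
            f"{len(dropped)} locus/loci without data in one group excluded from D_A",
            stacklevel=2,
        )
    if not shared:
        raise ValueError("no shared loci with data")
    total = 0.0
    for loc in shared:
        fx, fy = freqs_x[loc], freqs_y[loc]
        total += sum(math.sqrt(fx[a] * fy[a]) for a in fx if a in fy)
    return 1.0 - total / len(shared)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)


def da_distance_matrix(
    table: SSRGenotypeTable, by: str = "population"
) -> DistanceMatrix:
    """Pairwise ``D_A`` between groups (``by='population'|'species'``) or
    between individual multilocus genotypes (``by='individual'``)."""
    if by == "individual":
        groups = {s: np.array([i]) for i, s in enumerate(table.samples)}
    else:
        groups = table.group_indices(by)
    labels = list(groups)
    freqs = {g: allele_frequencies(table, idx) for g, idx in groups.items()}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m[i, j] = m[j, i] = nei_da(freqs[labels[i]], freqs[labels[j]])
    return DistanceMatrix(labels=labels, values=m)


def neighbor_joining(d: DistanceMatrix) -> UnrootedTree:
    """Saitou–Nei neighbour joining with the standard Q-criterion.

    A negative branch length at a join is clamped to zero and the deficit
    moved onto the sibling branch, preserving the path length between the
    joined pair.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    tree = UnrootedTree()
    active: list[int] = [tree.add_tip(lab) for lab in d.labels]
    dist = {
        (active[i], active[j]): float(d.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }

    def get(a: int, b: int) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    while len(active) > 2:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * get(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        # Clamp negatives, transferring the deficit to the sibling branch.
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        u = tree.add_node()
        tree.add_edge(u, a, la)
        tree.add_edge(u, b, lb)
        for c in active:
            if c in (a, b):
                continue
            dist[(u, c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [u]
    a, b = active
    tree.add_edge(a, b, max(get(a, b), 0.0))
    return tree


def bootstrap_support(
    table: SSRGenotypeTable,
    n_reps: int = 1000,
    seed: int = 0,
    by: str = "population",
) -> tuple[UnrootedTree, dict[frozenset[str], float]]:
    """Locus-resampling bootstrap support for the internal edges of the
    ``D_A`` neighbour-joining tree.

    Loci are resampled with replacement; each pseudo-replicate rebuilds the
    distance matrix and tree, and support is the fraction of replicates whose
    tree contains each original internal bipartition.
    """
    if table.n_loci < 2:
        raise ValueError("bootstrap needs >= 2 loci")
    tree = neighbor_joining(da_distance_matrix(table, by=by))
    targets = set(tree.bipartitions())
    hits = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        pick = rng.integers(0, table.n_loci, size=table.n_loci)
        boot = SSRGenotypeTable(
            samples=table.samples,
            population=table.population,
            species=table.species,
            loci=[f"L{i}_{table.loci[j]}" for i, j in enumerate(pick)],
            alleles=table.alleles[:, pick, :],
            motif_lengths=None,
        )
        btree = neighbor_joining(da_distance_matrix(boot, by=by))
        found = set(btree.bipartitions())
        for bp in targets & found:
            hits[bp] += 1
    support = {bp: hits[bp] / n_reps for bp in targets}
    return tree, support
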