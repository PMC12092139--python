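"""Synthetic datasets with the statistical structure of a sister-pair
selfing study.

Generates every input the analysis stages consume, without any downloads:

* SSR genotype tables for a sister pair — a chasmogamous (open-flowered,
  partially outcrossing) population with low but nonzero diversity, and a
  cleistogamous (obligately selfing) lineage founded from it recently enough
  that its multilocus genotypes are uniform with high probability;
* biallelic SNP matrices for two populations whose count of fixed
  differences scales with divergence time;
* per-sample transcript variant tables with configurable heterozygous-SNV
  density, nonsynonymous fraction and deleterious fraction;
* Brownian trait datasets on random birth–death trees with a built-in
  selfing effect, for exercising the PGLS stage.

Every generator is a pure function of its configuration: the same seed
yields identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import forward_sim
from .popgen_ssr import SSRGenotypeTable
from .snp_pipeline import SNPMatrix
from .snv_metrics import COLUMNS as VARIANT_COLUMNS
from .snv_metrics import VariantTable

__all__ = [
    "SSRScenario",
    "SNPScenario",
    "VariantScenario",
    "PGLSScenario",
    "make_sister_pair_ssr",
    "make_sister_pair_snps",
    "make_variant_tables",
    "make_pgls_dataset",
]


@dataclass(frozen=True)
class SSRScenario:
    """Sister-pair SSR sampling design.

    Defaults mirror the study system: a chasmogamous census of 250 with a
    high effective selfing rate (fly-mediated geitonogamy), a cleistogamous
    lineage of census 50 founded from a single chasmogamous individual a
    handful of generations before sampling, and an 18-locus panel of which 6
    are dinucleotide repeats mutating at the conservative
    Arabidopsis-derived rate.
    """

    n_chasmo: int = 250
    n_cleisto: int = 50
    sample_chasmo: int = 54
    sample_cleisto: int = 31
    selfing_rate_chasmo: float = 0.95
    n_loci: int = 18
    n_dinucleotide: int = 6
    mu_dinucleotide: float = 4.96e-5
    mu_other: float = 1.0e-5
    burn_in: int = 400
    divergence_generations: int = 10
    n_founder_alleles: int = 4
    chasmo_name: str = "chasmogamous"
    cleisto_name: str = "cleistogamous"


@dataclass(frozen=True)
class SNPScenario:
    """Two-population drift design for SNP matrices.

    ``divergence_generations`` controls how many fixed differences accrue;
    ``missing_rate`` introduces per-genotype dropout so missingness filters
    have something to do; ``artifact_het_fraction`` adds a small fraction of
    paralog-collapse-like sites that are heterozygous in nearly every
    sample, the signature the excess-heterozygosity filter removes.
    """

    n_snps: int = 375
    snps_per_locus: int = 3
    n_a: int = 60
    n_b: int = 34
    pop_size_a: int = 250
    pop_size_b: int = 50
    selfing_rate_a: float = 0.95
    selfing_rate_b: float = 1.0
    divergence_generations: int = 2000
    missing_rate: float = 0.1
    artifact_het_fraction: float = 0.02
    name_a: str = "chasmogamous"
    name_b: str = "cleistogamous"


@dataclass(frozen=True)
class VariantScenario:
    """Per-sample transcript variant-table design.

    Scores are drawn uniform in (-2.5, 0] for the neutral class and uniform
    in (-8, -2.5) for the deleterious class, so the realized deleterious
    fraction matches the configured one in expectation under the |score|>2.5
    rule.
    """

    n_samples: int = 9
    species: str = "species"
    n_transcripts: int = 500
    mean_len_bp: float = 1200.0
    snv_per_kb: float = 0.5
    nonsyn_fraction: float = 0.4
    deleterious_fraction: float = 0.3  # of nonsynonymous SNVs


@dataclass(frozen=True)
class PGLSScenario:
    """Brownian trait simulation on a random birth–death tree."""

    n_species: int = 20
    selfer_fraction: float = 0.5
    effect: float = -1.0
    sigma2: float = 0.25
    intercept: float = 2.0
    birth_rate: float = 1.0
    death_rate: float = 0.2


def _sample_founder_alleles(
    rng: np.random.Generator, n_ind: int, n_loci: int, n_alleles: int
) -> np.ndarray:
    """Initial allele-size pool: per locus, a few alleles spaced by whole
    repeat units around a locus-specific modal size."""
    base = rng.integers(150, 300, size=n_loci)
    g = np.zeros((n_ind, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        alleles = base[j] + 2 * np.arange(n_alleles)
        g[:, j, :] = rng.choice(alleles, size=(n_ind, 2))
    return g


def make_sister_pair_ssr(cfg: SSRScenario = SSRScenario(), seed: int = 0) -> SSRGenotypeTable:
    """Simulate a chasmogamous population and a recently founded
    cleistogamous lineage; return the combined sampled genotype table.

    The chasmogamous population evolves for ``burn_in`` generations under
    mixed mating from a polymorphic founder pool; a single individual then
    founds the cleistogamous lineage, which propagates by obligate selfing
    (s = 1) for ``divergence_generations`` while the chasmogamous population
    keeps evolving.  Samples are drawn without replacement from each.
    """
    rng = np.random.default_rng(seed)
    mu = np.full(cfg.n_loci, cfg.mu_other)
    mu[: cfg.n_dinucleotide] = cfg.mu_dinucleotide
    init = _sample_founder_alleles(rng, cfg.n_chasmo, cfg.n_loci, cfg.n_founder_alleles)
    chasmo = forward_sim.simulate_ssr_population(
        cfg.n_chasmo,
        cfg.n_loci,
        cfg.burn_in,
        mu,
        cfg.selfing_rate_chasmo,
        initial_genotypes=init,
        seed=int(rng.integers(2**31)),
    )
    founder = chasmo[rng.integers(cfg.n_chasmo)]
    cleisto_init = np.broadcast_to(founder, (cfg.n_cleisto, cfg.n_loci, 2)).copy()
    cleisto = forward_sim.simulate_ssr_population(
        cfg.n_cleisto,
        cfg.n_loci,
        cfg.divergence_generations,
        mu,
        1.0,
        initial_genotypes=cleisto_init,
        seed=int(rng.integers(2**31)),
    )
    chasmo = forward_sim.simulate_ssr_population(
        cfg.n_chasmo,
        cfg.n_loci,
        cfg.divergence_generations,
        mu,
        cfg.selfing_rate_chasmo,
        initial_genotypes=chasmo,
        seed=int(rng.integers(2**31)),
    )
    idx_c = rng.choice(cfg.n_chasmo, size=cfg.sample_chasmo, replace=False)
    idx_k = rng.choice(cfg.n_cleisto, size=cfg.sample_cleisto, replace=False)
    alleles = np.concatenate([chasmo[idx_c], cleisto[idx_k]], axis=0)
    # Sort each allele pair so tables are stable (pairs are unordered).
    alleles = np.sort(alleles, axis=-1)
    samples = [f"{cfg.chasmo_name}_{i:03d}" for i in range(cfg.sample_chasmo)] + [
        f"{cfg.cleisto_name}_{i:03d}" for i in range(cfg.sample_cleisto)
    ]
    species = np.array(
        [cfg.chasmo_name] * cfg.sample_chasmo + [cfg.cleisto_name] * cfg.sample_cleisto,
        dtype=object,
    )
    motif = np.array([2] * cfg.n_dinucleotide + [3] * (cfg.n_loci - cfg.n_dinucleotide))
    return SSRGenotypeTable(
        samples=samples,
        population=species.copy(),
        species=species,
        loci=[f"ssr{j+1:02d}" for j in range(cfg.n_loci)],
        alleles=alleles,
        motif_lengths=motif,
    )


def _drift_freqs(
    rng: np.random.Generator, p0: np.ndarray, n_lines: int, t: int
) -> np.ndarray:
    """Wright–Fisher drift of allele frequencies over ``t`` generations in a
    population of ``n_lines`` reproducing units (selfing lines drift with
    variance p(1-p)/N per generation, haploid-line resampling)."""
    p = p0.copy()
    for _ in range(t):
        p = rng.binomial(n_lines, p) / n_lines
    return p


def make_sister_pair_snps(cfg: SNPScenario = SNPScenario(), seed: int = 0) -> SNPMatrix:
    """Two-population SNP matrix whose fixed differences grow with
    divergence time.

    Ancestral alt-allele frequencies are drawn uniform on (0.05, 0.95); both
    daughter populations drift independently for ``divergence_generations``.
    Genotypes are sampled from each population's frequency with an
    inbreeding coefficient implied by its selfing rate (F = s/(2-s)), then
    thinned by random dropout.  A small fraction of sites is replaced by
    near-obligate heterozygotes to mimic collapsed paralogs.
    """
    if cfg.divergence_generations < 0:
        raise ValueError("divergence_generations must be >= 0")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    pa = _drift_freqs(rng, p0, cfg.pop_size_a, cfg.divergence_generations)
    pb = _drift_freqs(rng, p0, cfg.pop_size_b, cfg.divergence_generations)

    def genotypes(p: np.ndarray, n: int, s: float) -> np.ndarray:
        f = s / (2.0 - s) if s < 2 else 1.0
        # Genotype frequencies with inbreeding F.
        p_ = np.broadcast_to(p, (n, cfg.n_snps))
        hom_alt = p_**2 + f * p_ * (1 - p_)
        het = 2 * p_ * (1 - p_) * (1 - f)
        u = rng.random((n, cfg.n_snps))
        g = np.full((n, cfg.n_snps), 0, dtype=np.int8)
        g[u < hom_alt] = 2
        g[(u >= hom_alt) & (u < hom_alt + het)] = 1
        return g

    ga = genotypes(pa, cfg.n_a, cfg.selfing_rate_a)
    gb = genotypes(pb, cfg.n_b, cfg.selfing_rate_b)
    g = np.concatenate([ga, gb], axis=0)

    n_art = int(round(cfg.artifact_het_fraction * cfg.n_snps))
    if n_art:
        art_sites = rng.choice(cfg.n_snps, size=n_art, replace=False)
        for j in art_sites:
            het = rng.random(g.shape[0]) < 0.9
            g[het, j] = 1
    drop = rng.random(g.shape) < cfg.missing_rate
    g[drop] = -1

    n_loci = -(-cfg.n_snps // cfg.snps_per_locus)
    locus_ids = np.array(
        [f"locus{j // cfg.snps_per_locus + 1:04d}" for j in range(cfg.n_snps)],
        dtype=object,
    )
    pos = np.array([j % cfg.snps_per_locus + 1 for j in range(cfg.n_snps)])
    del n_loci
    samples = [f"{cfg.name_a}_{i:03d}" for i in range(cfg.n_a)] + [
        f"{cfg.name_b}_{i:03d}" for i in range(cfg.n_b)
    ]
    species = np.array([cfg.name_a] * cfg.n_a + [cfg.name_b] * cfg.n_b, dtype=object)
    return SNPMatrix(
        samples=samples,
        species=species,
        population=species.copy(),
        snp_ids=[f"snp{j+1:04d}" for j in range(cfg.n_snps)],
        locus_ids=locus_ids,
        pos_in_locus=pos,
        genotypes=g,
    )


def make_variant_tables(cfg: VariantScenario = VariantScenario(), seed: int = 0) -> VariantTable:
    """Per-sample heterozygous-SNV tables with Poisson SNV counts.

    Each sample gets the same transcript set (lengths drawn once per
    scenario); SNV counts per transcript are Poisson at the configured
    per-kb density, effect classes are Bernoulli(nonsyn fraction) and
    nonsynonymous scores come from threshold-respecting class-conditional
    uniform distributions.
    """
    if cfg.snv_per_kb < 0:
        raise ValueError("snv_per_kb must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        rng.gamma(4.0, cfg.mean_len_bp / 4.0, size=cfg.n_transcripts).astype(int), 300
    )
    rows: list[tuple] = []
    for i in range(cfg.n_samples):
        sample = f"{cfg.species}_{i+1:02d}"
        counts = rng.poisson(cfg.snv_per_kb * lengths / 1000.0)
        snv_no = 0
        for t_idx in range(cfg.n_transcripts):
            tid = f"tr{t_idx+1:05d}"
            if counts[t_idx] == 0:
                rows.append((sample, cfg.species, tid, int(lengths[t_idx]), None, None, None))
                continue
            for _ in range(counts[t_idx]):
                snv_no += 1
                nonsyn = rng.random() < cfg.nonsyn_fraction
                if nonsyn:
                    if rng.random() < cfg.deleterious_fraction:
                        score = rng.uniform(-8.0, -2.5)
                    else:
                        score = rng.uniform(-2.5, 0.0)
                    rows.append(
                        (sample, cfg.species, tid, int(lengths[t_idx]),
                         f"snv{snv_no:06d}", "nonsynonymous", round(score, 3))
                    )
                else:
                    rows.append(
                        (sample, cfg.species, tid, int(lengths[t_idx]),
                         f"snv{snv_no:06d}", "synonymous", None)
                    )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["score"] = df["score"].astype(float)
    return VariantTable(df)


def make_pgls_dataset(
    cfg: PGLSScenario = PGLSScenario(), seed: int = 0
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Random birth–death tree plus Brownian traits with a selfing effect.

    Traits follow ``y = intercept + effect * selfing + e`` with
    ``e ~ MVN(0, sigma2 * C)`` for the tree's Brownian covariance ``C``.
    Selfer status is assigned to a random subset of tips.
    """
    if cfg.n_species < 4:
        raise ValueError("need >= 4 species")
    pyrng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=cfg.death_rate,
        num_extant_tips=cfg.n_species,
        rng=pyrng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i+1:02d}"
        # The sampler stops at a speciation event, leaving its two newest
        # tips on zero-length branches; a uniform tip extension keeps the
        # tree ultrametric and the Brownian covariance positive definite.
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.1
    from .pgls import brownian_covariance

    names, C = brownian_covariance(tree)
    rng = np.random.default_rng(seed)
    n_self = int(round(cfg.selfer_fraction * cfg.n_species))
    selfers = rng.choice(cfg.n_species, size=n_self, replace=False)
    selfing = np.zeros(cfg.n_species)
    selfing[selfers] = 1.0
    L = np.linalg.cholesky(C)
    e = np.sqrt(cfg.sigma2) * (L @ rng.standard_normal(cfg.n_species))
    y = cfg.intercept + cfg.effect * selfing + e
    traits = pd.DataFrame(
        {"selfing": selfing.astype(int), "metric": y}, index=pd.Index(names, name="species")
    )
    return tree, traits
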