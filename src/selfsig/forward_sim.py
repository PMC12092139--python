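"""Forward-time Monte-Carlo simulation of SSR evolution under selfing.

Two simulators live here:

* :func:`simulate_uniformity` — tracks whether a set of independent selfing
  lines still shares the ancestral multilocus genotype, either in an
  *effective* mode (each line/locus draws an eventually-fixed mutation with
  probability ``mu`` per generation, mirroring the analytic clock) or in an
  *explicit* diploid mode (per-copy stepwise mutation, offspring formed by
  random union of two gametes from the same parent).  The effective mode is
  the Monte-Carlo counterpart of the analytic ``P_i(t)`` and serves as its
  independent oracle; the explicit mode validates the half-fixation argument
  end to end.

* :func:`simulate_ssr_population` — a Wright–Fisher population of diploids
  with a mixed mating system (selfing rate ``s``), stepwise mutation and
  optional instantaneous founder events; the engine behind synthetic SSR
  genotype tables.

All randomness flows through a single ``numpy.random.Generator`` seeded from
the configuration, so identical configurations reproduce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .clock import MutationModel, population_uniformity_prob

__all__ = [
    "SimConfig",
    "UniformityCurve",
    "simulate_uniformity",
    "fixation_probability_of_new_mutation",
    "selfing_offspring_distribution",
    "simulate_ssr_population",
]

Mode = Literal["effective", "explicit"]
Criterion = Literal["fixed_only", "observed_genotype"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a genotype-uniformity simulation.

    ``mu`` is the fixation-effective per-locus rate in effective mode and the
    per-copy (haploid) rate in explicit mode; under the half-fixation
    argument the same number plays both roles.
    """

    model: MutationModel
    ne: int
    t_max: int
    n_reps: int = 1000
    mode: Mode = "effective"
    uniformity_criterion: Criterion = "fixed_only"
    mutation_model: Literal["stepwise", "infinite_alleles"] = "stepwise"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if self.mode not in ("effective", "explicit"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.uniformity_criterion not in ("fixed_only", "observed_genotype"):
            raise ValueError(f"unknown criterion {self.uniformity_criterion!r}")
        if self.mutation_model not in ("stepwise", "infinite_alleles"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")


@dataclass
class UniformityCurve:
    """Per-generation Monte-Carlo estimate of the uniformity probability.

    ``estimate[t]`` is the fraction of replicates in which no line had
    deviated from the ancestral multilocus genotype by generation ``t``
    (index 0 is generation 0, always 1.0); ``se`` is the binomial standard
    error of that fraction.
    """

    generations: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    config: SimConfig = field(repr=False, default=None)

    def analytic(self) -> np.ndarray:
        """Analytic ``P_i(t)`` on the same generation grid."""
        m = self.config.model
        return np.array(
            [population_uniformity_prob(m, self.config.ne, int(t)) for t in self.generations]
        )


def _curve_from_deviation_times(dev_time: np.ndarray, cfg: SimConfig) -> UniformityCurve:
    # dev_time[i] = generation of first deviation in replicate i, or t_max+1.
    gens = np.arange(cfg.t_max + 1)
    alive = (dev_time[None, :] > gens[:, None]).mean(axis=1)
    se = np.sqrt(alive * (1.0 - alive) / cfg.n_reps)
    return UniformityCurve(generations=gens, estimate=alive, se=se, config=cfg)


def _simulate_effective(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_channels = cfg.ne * cfg.model.n_loci
    dev_time = np.full(cfg.n_reps, cfg.t_max + 1, dtype=np.int64)
    active = np.arange(cfg.n_reps)
    for t in range(1, cfg.t_max + 1):
        if active.size == 0:
            break
        hits = rng.binomial(n_channels, cfg.model.mu, size=active.size) > 0
        dev_time[active[hits]] = t
        active = active[~hits]
    return dev_time


def _simulate_explicit(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Explicit diploid selfing lines with per-copy stepwise mutation.

    State is an integer offset from the ancestral repeat number per allele
    copy, shape (replicates, lines, loci, 2).  Each generation: mutation on
    parental copies, then one selfed offspring per line by random union of
    two gametes drawn from that parent.
    """
    mu = cfg.model.mu
    l = cfg.model.n_loci
    dev_time = np.full(cfg.n_reps, cfg.t_max + 1, dtype=np.int64)
    rep_ids = np.arange(cfg.n_reps)
    g = np.zeros((cfg.n_reps, cfg.ne, l, 2), dtype=np.int32)
    novel = 1  # next label for infinite-alleles mode

    for t in range(1, cfg.t_max + 1):
        if rep_ids.size == 0:
            break
        # Mutation: number of mutated copies across the whole array is
        # Binomial(n_copies, mu); placement uniform over copies.
        n_mut = rng.binomial(g.size, mu)
        if n_mut:
            idx = rng.integers(0, g.size, size=n_mut)
            if cfg.mutation_model == "stepwise":
                steps = rng.choice(np.array([-1, 1], dtype=np.int32), size=n_mut)
                np.add.at(g.reshape(-1), idx, steps)
            else:
                g.reshape(-1)[idx] = np.arange(novel, novel + n_mut, dtype=np.int32)
                novel += n_mut
        # Selfing: homozygous loci are unchanged by gamete sampling, so only
        # heterozygous loci need draws.
        a, b = g[..., 0], g[..., 1]
        het = a != b
        k = int(het.sum())
        if k:
            ha, hb = a[het], b[het]
            pick0 = rng.integers(0, 2, size=k).astype(bool)
            pick1 = rng.integers(0, 2, size=k).astype(bool)
            a[het] = np.where(pick0, hb, ha)
            b[het] = np.where(pick1, hb, ha)
        # Deviation check.
        if cfg.uniformity_criterion == "fixed_only":
            dev = np.any((g[..., 0] == g[..., 1]) & (g[..., 0] != 0), axis=(1, 2))
        else:
            dev = np.any(g != 0, axis=(1, 2, 3))
        if dev.any():
            dev_time[rep_ids[dev]] = t
            keep = ~dev
            g = g[keep]
            rep_ids = rep_ids[keep]
    return dev_time


def simulate_uniformity(config: SimConfig) -> UniformityCurve:
    """Monte-Carlo estimate of the genotype-uniformity probability curve.

    A replicate counts as uniform at generation ``t`` if no line has
    deviated from the ancestral multilocus genotype at any generation up to
    ``t`` under the configured criterion (``fixed_only``: only a new allele
    at homozygosity counts; ``observed_genotype``: any non-ancestral
    genotype, heterozygotes included).
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "effective":
        dev_time = _simulate_effective(config, rng)
    else:
        dev_time = _simulate_explicit(config, rng)
    return _curve_from_deviation_times(dev_time, config)


def fixation_probability_of_new_mutation(
    n_reps: int, seed: int = 0, max_generations: int = 10_000
) -> float:
    """Fraction of new heterozygous neutral mutations that fix under selfing.

    Each replicate starts one Aa line and follows it by random union of two
    gametes per generation until the mutant allele is fixed (aa... i.e. both
    copies mutant) or lost; the expected fraction fixed is 1/2.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    unresolved = n_reps
    fixed = 0
    for _ in range(max_generations):
        if unresolved == 0:
            break
        # Two gametes, each carrying the mutant allele with probability 1/2.
        gametes = rng.integers(0, 2, size=(unresolved, 2))
        n_mut = gametes.sum(axis=1)
        fixed += int((n_mut == 2).sum())
        unresolved = int((n_mut == 1).sum())
    return fixed / n_reps


def selfing_offspring_distribution() -> dict[str, float]:
    """Exact offspring genotype distribution of a selfed Aa parent.

    Enumerates the four equiprobable ordered gamete pairs; returns
    ``{"AA": 1/4, "Aa": 1/2, "aa": 1/4}``.
    """
    counts = {"AA": 0, "Aa": 0, "aa": 0}
    for g1 in "Aa":
        for g2 in "Aa":
            if g1 == g2 == "A":
                counts["AA"] += 1
            elif g1 == g2 == "a":
                counts["aa"] += 1
            else:
                counts["Aa"] += 1
    return {k: v / 4.0 for k, v in counts.items()}


def simulate_ssr_population(
    n_individuals: int,
    n_loci: int,
    t: int,
    mu: float | np.ndarray,
    selfing_rate: float,
    initial_genotypes: np.ndarray | None = None,
    founder_events: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Evolve a diploid Wright–Fisher population with mixed mating.

    Parameters
    ----------
    n_individuals : int
        Constant census size N (one surviving offspring cohort per
        generation).
    n_loci : int
        Number of SSR loci.
    t : int
        Generations to simulate.
    mu : float or array of shape (n_loci,)
        Per-copy stepwise mutation rate, scalar or per locus.
    selfing_rate : float
        Probability ``s`` that an offspring is produced by selfing; otherwise
        two parents are drawn at random (outcrossing, parents may coincide by
        chance as in standard Wright–Fisher sampling).
    initial_genotypes : array (N, n_loci, 2) of int, optional
        Starting allele sizes; defaults to a monomorphic population (size 0
        offsets everywhere).
    founder_events : list of (generation, k), optional
        At each listed generation the parent pool is restricted to ``k``
        randomly chosen individuals (instantaneous founder bottleneck).
    seed : int
        RNG seed.

    Returns
    -------
    ndarray of shape (N, n_loci, 2)
        Final allele sizes (integer repeat offsets).
    """
    if n_individuals < 1:
        raise ValueError("population size must be >= 1")
    if not (0.0 <= selfing_rate <= 1.0):
        raise ValueError("selfing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_individuals
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n_loci,))
    if initial_genotypes is None:
        g = np.zeros((n, n_loci, 2), dtype=np.int32)
    else:
        g = np.array(initial_genotypes, dtype=np.int32, copy=True)
        if g.shape != (n, n_loci, 2):
            raise ValueError(
                f"initial_genotypes must have shape {(n, n_loci, 2)}, got {g.shape}"
            )
    events = dict(founder_events or [])
    for gen in range(1, t + 1):
        pool = np.arange(n)
        if gen in events:
            k = events[gen]
            if not (1 <= k <= n):
                raise ValueError(f"founder size {k} outside [1, {n}]")
            pool = rng.choice(n, size=k, replace=False)
        selfed = rng.random(n) < selfing_rate
        p1 = pool[rng.integers(0, pool.size, size=n)]
        p2 = np.where(selfed, p1, pool[rng.integers(0, pool.size, size=n)])
        # One gamete per parent: per locus, pick one of the two copies.
        c1 = rng.integers(0, 2, size=(n, n_loci))
        c2 = rng.integers(0, 2, size=(n, n_loci))
        rows = np.arange(n)[:, None]
        cols = np.arange(n_loci)[None, :]
        offspring = np.stack(
            [g[p1[:, None], cols, c1], g[p2[:, None], cols, c2]], axis=-1
        )
        del rows
        # Stepwise mutation on the new cohort, per-locus rates.
        mut = rng.random(offspring.shape) < mu_arr[None, :, None]
        n_mut = int(mut.sum())
        if n_mut:
            steps = rng.choice(np.array([-1, 1], dtype=np.int32), size=n_mut)
            offspring[mut] += steps
        g = offspring
    return g
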