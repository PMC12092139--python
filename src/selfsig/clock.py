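"""Genotype-uniformity clock for obligately selfing lineages.

In a lineage that reproduces exclusively by self-fertilization, every
individual is an independent inbred line.  A new microsatellite (SSR) allele
arises in a line with probability ``2*mu`` per locus per generation (two
allele copies, per-copy rate ``mu``), and under neutral selfed propagation
half of those new alleles eventually reach homozygosity — so the rate at
which a line acquires a *fixed* new allele is ``mu`` per locus per
generation.  The probability that a single line still carries the ancestral
multilocus genotype after ``t`` generations at ``l`` loci is

    P_t = (1 - mu) ** (l * t)

and the probability that *all* of ``Ne`` independent lines do is

    P_i = P_t ** Ne

Observing a perfectly uniform multilocus genotype across a population
therefore bounds how long ago the population can have been founded: the
clock reports the first generation at which ``P_i`` drops below a chosen
probability threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MutationModel",
    "GenerationTimeRange",
    "DEFAULT_MU",
    "DEFAULT_N_LOCI",
    "MU_SENSITIVITY_RANGE",
    "prob_no_new_fixed_allele",
    "prob_population_uniform",
    "generations_to_threshold",
    "calendar_window",
    "uniformity_curve",
]

#: Lowest directly estimated dinucleotide SSR mutation rate in *Arabidopsis
#: thaliana* mutation-accumulation lines; the conservative default.
DEFAULT_MU = 4.96e-5

#: Number of dinucleotide-repeat loci in the default marker panel.
DEFAULT_N_LOCI = 6

#: Empirical range of dinucleotide SSR mutation rates (motif- and
#: repeat-number-dependent), usable as sensitivity-scan bounds.
MU_SENSITIVITY_RANGE = (5.0e-5, 2.0e-3)


@dataclass(frozen=True)
class MutationModel:
    """Fixation-effective SSR mutation model for a selfing line.

    Parameters
    ----------
    mu : float
        Per-locus per-generation probability that a new allele *destined to
        fix* arises in a line.  Derived from the per-copy rate via the
        half-fixation argument: ``2*mu_copy * 1/2 = mu_copy``, so the
        effective rate numerically equals the per-copy (haploid) rate.
    n_loci : int
        Number of SSR loci ``l`` scored.
    """

    mu: float = DEFAULT_MU
    n_loci: int = DEFAULT_N_LOCI

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu < 1.0):
            raise ValueError(f"mu must be in [0, 1), got {self.mu}")
        if self.n_loci < 1:
            raise ValueError(f"n_loci must be >= 1, got {self.n_loci}")


@dataclass(frozen=True)
class GenerationTimeRange:
    """Calendar time per generation, as a (min, max) range in years."""

    min_years: float = 5.0
    max_years: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_years <= self.max_years):
            raise ValueError(
                f"require 0 < min_years <= max_years, got "
                f"({self.min_years}, {self.max_years})"
            )


def prob_no_new_fixed_allele(model: MutationModel, t: int) -> float:
    """Probability ``P_t`` that one selfing line fixes no new allele in ``t``
    generations across all loci.

    Computed in log space as ``exp(l * t * log1p(-mu))`` so that very large
    exponents do not underflow prematurely.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    return math.exp(model.n_loci * t * math.log1p(-model.mu))


def prob_population_uniform(p_t: float, ne: int) -> float:
    """Probability ``P_i = P_t ** Ne`` that all ``ne`` independent selfing
    lines retain the ancestral multilocus genotype."""
    if not (0.0 <= p_t <= 1.0):
        raise ValueError(f"p_t must be a probability in [0, 1], got {p_t}")
    if ne < 1:
        raise ValueError(f"ne must be >= 1, got {ne}")
    if p_t == 0.0:
        return 0.0
    return math.exp(ne * math.log(p_t))


def population_uniformity_prob(model: MutationModel, ne: int, t: int) -> float:
    """``P_i(t)`` computed directly from the model (log-space throughout)."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if ne < 1:
        raise ValueError(f"ne must be >= 1, got {ne}")
    return math.exp(model.n_loci * t * ne * math.log1p(-model.mu))


def generations_to_threshold(
    model: MutationModel, ne: int, alpha: float = 0.05
) -> int:
    """Smallest integer ``t*`` with ``P_i(t*) < alpha`` (strictly below).

    Uses the closed form ``ceil(ln(alpha) / (l * ne * ln(1 - mu)))`` and then
    checks the strict-inequality boundary explicitly: if ``P_i`` at the
    closed-form candidate equals ``alpha`` exactly, uniformity has not yet
    fallen *below* the threshold and ``t*`` is incremented by one.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if ne < 1:
        raise ValueError(f"ne must be >= 1, got {ne}")
    if model.mu == 0.0:
        raise ValueError(
            "mu = 0: a uniform genotype persists forever; no finite threshold"
        )
    rate = model.n_loci * ne * math.log1p(-model.mu)  # < 0
    t = math.ceil(math.log(alpha) / rate)
    # Guard the boundary both ways: floating-point ceil can land one step
    # early or exactly on the threshold.
    while population_uniformity_prob(model, ne, t) >= alpha:
        t += 1
    while t > 0 and population_uniformity_prob(model, ne, t - 1) < alpha:
        t -= 1
    return t


def calendar_window(t: int, g: GenerationTimeRange) -> tuple[float, float]:
    """Convert a generation count into a (min, max) calendar window in years."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    return (t * g.min_years, t * g.max_years)


def uniformity_curve(model: MutationModel, ne: int, t_max: int) -> list[float]:
    """Analytic ``P_i(t)`` for ``t = 0 .. t_max`` inclusive."""
    return [population_uniformity_prob(model, ne, t) for t in range(t_max + 1)]
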