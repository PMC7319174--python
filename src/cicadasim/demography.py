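"""Nymph growth, emergence eligibility and safe-site newborn recruitment.

Underground nymphs grow by one random positive increment per year, drawn
from a log-normal distribution ``exp(N(mu, sigma^2))``, until they reach the
target body size ``s*`` (no further growth past the threshold).  The default
parameters are calibrated so that essentially every nymph reaches ``s*``
within ten years, which keeps all cycle lengths of ten or more years strictly
periodic.

Newborns compete for empty feeding cells under a safe-site model: established
nymphs are invulnerable, and each newborn lands in a random cell, so the
number of competitors sharing its cell is Poisson-distributed.  The resulting
establishment probability is

    P_est = (1 - N1/N) * sum_{k=0}^{N0-1} e^{-lam} lam^k / k! * 1/(k+1),

with ``lam = N0/N``, where ``N1`` established nymphs occupy cells out of
``N`` in the patch and ``N0`` newborns arrive; ``P_est = 0`` whenever
``N1 > N``.  Establishment is decided by an independent Bernoulli trial per
newborn, so the pool can transiently exceed ``N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .genetics import EmergenceKind, Genotype, Phenotype

__all__ = [
    "GrowthParams",
    "Nymph",
    "RecruitmentInput",
    "grow_one_year",
    "emergence_eligible",
    "establishment_probability",
    "recruit_newborns",
    "expected_size_at_age",
    "crossing_age_pmf",
]


@dataclass(frozen=True)
class GrowthParams:
    """Log-normal annual growth increment and emergence size threshold.

    ``mu``/``sigma`` are the mean and standard deviation on the log scale, so
    the mean annual increment is ``exp(mu + sigma^2/2)``.  The defaults used
    by the simulation live in ``defaults.yaml``.
    """

    mu: float
    sigma: float
    size_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.size_threshold <= 0:
            raise ValueError("size_threshold must be > 0")

    @property
    def mean_increment(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2.0)


@dataclass
class Nymph:
    """A single underground nymph (used by the reference engine and tests)."""

    genotype: Genotype
    phenotype: Phenotype
    age: int = 0
    body_size: float = 0.0
    #: Year-flag for size-based emergers: True once the threshold was reached
    #: in a *previous* year ("emerges the following summer").
    ready_last_year: bool = False


@dataclass(frozen=True)
class RecruitmentInput:
    """Patch occupancy seen by arriving newborns."""

    N1: int  # established older nymphs
    N0: int  # arriving newborns
    N: int  # feeding cells in the patch

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.N1 < 0 or self.N0 < 0:
            raise ValueError("counts must be non-negative")


def grow_one_year(nymph: Nymph, params: GrowthParams, rng: np.random.Generator) -> Nymph:
    """Age the nymph by one year and grow it unless already at the threshold.

    Growth past the target size is irrelevant to emergence, so size is frozen
    at its first value >= ``s*``.  The size-based "ready last year" flag is
    updated before this year's increment is applied.
    """
    was_ready = nymph.body_size >= params.size_threshold
    size = nymph.body_size
    if not was_ready:
        if params.sigma == 0.0:
            size += math.exp(params.mu)
        else:
            size += float(rng.lognormal(params.mu, params.sigma))
    return replace(nymph, age=nymph.age + 1, body_size=size, ready_last_year=was_ready)


def emergence_eligible(nymph: Nymph, size_threshold: float) -> bool:
    """Whether the nymph emerges this summer (delays are handled upstream).

    Age-based phenotypes emerge at the first opportunity once both the
    minimum age and the size threshold are met.  Size-based phenotypes emerge
    the summer *after* first reaching the threshold.
    """
    if nymph.phenotype.kind is EmergenceKind.AGE:
        return (
            nymph.age >= nymph.phenotype.emergence_age
            and nymph.body_size >= size_threshold
        )
    return nymph.ready_last_year


def establishment_probability(inp: RecruitmentInput) -> float:
    """Safe-site establishment probability of one arriving newborn.

    Evaluates the truncated sum exactly through the Poisson CDF identity
    ``sum_{k=0}^{N0-1} e^-lam lam^k/k! / (k+1) = (F(N0; lam) - e^-lam)/lam``
    (index shift ``j = k+1``), which is numerically stable for any ``N0``.
    ``N0 = 0`` returns 1 by convention (the value is never sampled).
    """
    if inp.N1 > inp.N:
        return 0.0
    if inp.N0 == 0:
        return 1.0
    lam = inp.N0 / inp.N
    empty_frac = 1.0 - inp.N1 / inp.N
    # special.pdtr(N0, lam) is the Poisson CDF at N0 — the truncated sum
    # shifted by one index — evaluated in one stable C call
    partial = (float(special.pdtr(inp.N0, lam)) - math.exp(-lam)) / lam
    return float(min(1.0, empty_frac * partial))


def recruit_newborns(
    newborns: list[Nymph],
    patch_occupancy: RecruitmentInput,
    rng: np.random.Generator,
) -> list[Nymph]:
    """Independent Bernoulli establishment trial per newborn; survivors join
    the patch (the total may exceed ``N``), the rest die."""
    if any(n.age != 0 for n in newborns):
        raise ValueError("recruits must be newborns (age 0)")
    p_est = establishment_probability(patch_occupancy)
    if p_est >= 1.0:
        return list(newborns)
    keep = rng.random(len(newborns)) < p_est
    return [n for n, k in zip(newborns, keep) if k]


def expected_size_at_age(age: int, params: GrowthParams) -> float:
    """Initial body size assigned to a founder of the given age: the expected
    cumulative increment, capped at the threshold."""
    return min(age * params.mean_increment, params.size_threshold)


@lru_cache(maxsize=64)
def _crossing_pmf_cached(
    mu: float, sigma: float, threshold: float, start_size: float,
    max_years: int, n_bins: int,
) -> tuple[float, ...]:
    # Distribution of size-below-threshold on a uniform grid over
    # [0, threshold); mass pushed past the threshold in year a is the
    # probability of first crossing at age a.  Increment pmf from CDF
    # differences of the log-normal; the tail >= threshold is handled via sf.
    if start_size >= threshold:
        raise ValueError("already past threshold")
    if sigma == 0.0:
        # Deterministic increments: crossing age is a point mass.
        inc = math.exp(mu)
        years = max(1, math.ceil((threshold - start_size) / inc - 1e-12))
        pmf = [0.0] * max(years, 1)
        pmf[years - 1] = 1.0
        return tuple(pmf)
    width = threshold / n_bins
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    edges = np.arange(n_bins + 1) * width
    inc_pmf = np.diff(dist.cdf(edges))  # increment mass below the threshold
    state = np.zeros(n_bins)
    state[min(n_bins - 1, int(start_size / width))] = 1.0
    pmf: list[float] = []
    for _ in range(max_years):
        # mass leaving [0, threshold) this year is the crossing probability;
        # computing it as lost mass conserves total probability exactly
        new_state = np.convolve(state, inc_pmf)[:n_bins]
        pmf.append(float(state.sum() - new_state.sum()))
        state = new_state
        if state.sum() < 1e-12:
            break
    # Any residual sub-threshold mass is folded into the last entry so the
    # pmf sums to 1.
    total = sum(pmf)
    pmf[-1] += max(0.0, 1.0 - total)
    return tuple(pmf)


def crossing_age_pmf(
    params: GrowthParams,
    start_size: float = 0.0,
    start_age: int = 0,
    max_years: int = 64,
    n_bins: int = 4096,
) -> np.ndarray:
    """Distribution of the age at which a nymph first reaches the threshold.

    Entry ``j`` of the returned array is the probability that a nymph of age
    ``start_age`` and current size ``start_size`` first reaches ``s*`` during
    the growth season of age ``start_age + 1 + j``.  Crossing ages are i.i.d.
    across nymphs, which is what lets the cohort engine replace per-nymph
    size bookkeeping by one multinomial draw per cohort.

    Computed by numerically convolving the sub-threshold size distribution
    with the log-normal increment law on a fine grid; an empty array means
    the nymph has already crossed.
    """
    if start_size >= params.size_threshold:
        return np.array([])
    del start_age  # ages are relative; kept in the signature for clarity
    return np.array(
        _crossing_pmf_cached(
            params.mu, params.sigma, params.size_threshold,
            float(start_size), max_years, n_bins,
        )
    )
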