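"""Yearly simulation loop of the patch-structured cicada population.

One simulated year applies, in order: (1) nymph growth, (2) emergence of all
eligible nymphs (unless a population-wide delay is active), (3) predation on
each patch's emerging adults, (4) migration of surviving adults to a
uniformly chosen patch, (5) mating and reproduction within the post-migration
patch, (6) adult death, (7) safe-site recruitment of newborns, and (8) the
delay-state update.  A simulation starts with a burn-in interval during
which migration and mutation are disabled, delays cannot start, and predator
density ramps linearly from zero, letting every patch settle into its
demographic equilibrium before the patches are coupled.

Two interchangeable execution strategies are provided:

``mode="individual"``
    The reference implementation: every nymph and adult is an explicit array
    row and every stochastic decision (growth increment, survival, migration,
    mate choice, allele transmission, rounding) is an independent per-capita
    draw.

``mode="cohort"``
    The production implementation: identically distributed individuals are
    aggregated into cohorts keyed by genotype, phenotype, birth year and
    first-eligible emergence age.  Per-capita Bernoulli and uniform draws
    become binomial/multinomial draws on cohort counts, and per-nymph size
    bookkeeping is replaced by one multinomial draw from the exact
    first-crossing-age distribution of the cumulative growth process.  Every
    aggregation step is an exact distributional equivalent of the
    per-individual rule, which the test suite verifies empirically.
"""

from __future__ import annotations

import heapq
import math
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .config import SimConfig
from .demography import (
    GrowthParams,
    RecruitmentInput,
    crossing_age_pmf,
    establishment_probability,
    expected_size_at_age,
)
from .genetics import SIZE_CODE, mutate_allele_code
from .predation import (
    EmergenceEvent,
    apply_predation,
    ramped_predator_density,
    survival_probability,
)

__all__ = [
    "CensusRecord",
    "RunResult",
    "SimulationState",
    "initialize",
    "run_year",
    "run_simulation",
    "sample_father_genotype",
]

ClassKey = tuple[int, int, int]  # (allele_lo, allele_hi, phenotype_code)


# --------------------------------------------------------------------------
# records and results


@dataclass
class CensusRecord:
    """Patch composition at the end of a year in which it changed.

    Composition is constant between records, so the list of records is a
    step-function representation of each patch's history.  ``class_counts``
    maps ``(allele_lo, allele_hi, phenotype)`` to a nymph count.
    """

    year: int
    patch: int
    class_counts: dict[ClassKey, int]

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    @property
    def het(self) -> int:
        return sum(n for (lo, hi, _p), n in self.class_counts.items() if lo != hi)

    @property
    def phen_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (_lo, _hi, phen), n in self.class_counts.items():
            out[phen] = out.get(phen, 0) + n
        return out


@dataclass
class RunResult:
    config: SimConfig
    seed: int | None
    mode: str
    years_run: int
    migration_start_year: int
    founding_cycles: list[int | None]
    events: list[EmergenceEvent]
    census: list[CensusRecord]
    delay_starts: list[int]
    final_census: dict[int, dict[ClassKey, int]]


# --------------------------------------------------------------------------
# scenario layouts

_RANDOM_AGE_SCENARIOS = {"random_ages", "random_ages_with_delays", "clonal"}


def _scenario_layout(config: SimConfig, rng: np.random.Generator):
    """Founder groups per patch: list over patches of [(cycle, age, count)],
    plus the founding-cycle label of each patch."""
    fill = config.initial_fill
    if config.scenario == "single_patch":
        per = max(1, round(fill * config.N / len(config.cycle_lengths)))
        groups = [[(c, 0, per) for c in config.cycle_lengths]]
        return groups, [None]
    if config.scenario == "twenty_patch_random":
        n = config.n_patches
        cycles = [int(rng.choice(config.cycle_lengths)) for _ in range(n)]
        groups = [
            [(c, int(rng.integers(0, c)), round(fill * config.N))] for c in cycles
        ]
        return groups, cycles
    count = round(fill * config.N)
    groups = []
    labels = []
    for c in config.cycle_lengths:
        if config.scenario == "newborn_start":
            age = 0
        elif config.scenario in _RANDOM_AGE_SCENARIOS:
            age = int(rng.integers(0, c))
        else:  # pragma: no cover - validated in SimConfig
            raise ValueError(config.scenario)
        groups.append([(c, age, count)])
        labels.append(c)
    return groups, labels


# --------------------------------------------------------------------------
# cohort patch

@lru_cache(maxsize=4096)
def _eligible_age_distribution(
    growth: GrowthParams, phen: int, start_size: float, start_age: int
) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Distribution of the first-eligible emergence age for one nymph.

    For an age-based phenotype ``e`` the first-eligible age is ``max(e, T)``
    where ``T`` is the (random) age of first threshold crossing; for the
    size-based phenotype it is ``T + 1`` (emerge the summer after crossing).
    Equal eligible ages are collapsed so the leading entry usually carries
    almost all of the mass.
    """
    if start_size >= growth.size_threshold:
        # Already past the threshold before the simulation starts.
        if phen == SIZE_CODE:
            return (start_age + 1,), (1.0,)
        return (max(phen, start_age),), (1.0,)
    pmf = crossing_age_pmf(growth, start_size=start_size)
    pmf = pmf / pmf.sum()
    agg: dict[int, float] = {}
    for j, prob in enumerate(pmf):
        if prob <= 0.0:
            continue
        t = start_age + 1 + j
        elig = t + 1 if phen == SIZE_CODE else max(phen, t)
        agg[elig] = agg.get(elig, 0.0) + float(prob)
    ages = tuple(sorted(agg))
    probs = tuple(agg[a] for a in ages)
    return ages, probs


class CohortPatch:
    """Nymph pool aggregated into exchangeable cohorts.

    A nymph's future is fully determined by its genotype class and the first
    year it is eligible to emerge (``birth_year + eligible_age``, drawn once
    at recruitment from the crossing-age distribution), so cohorts are keyed
    by ``(allele_lo, allele_hi, phenotype, emergence_year)`` and nymphs of
    the same class that are phase-locked merge into one cohort.  Class
    totals and the next emergence year are maintained incrementally.
    """

    __slots__ = (
        "growth", "cohorts", "classes", "count", "next_emergence_year",
        "_heap", "_elig_cache",
    )

    def __init__(self, growth: GrowthParams):
        self.growth = growth
        self.cohorts: dict[tuple[int, int, int, int], int] = {}
        self.classes: dict[ClassKey, int] = {}
        self.count = 0
        self.next_emergence_year: int | None = None
        self._heap: list[tuple[int, tuple[int, int, int, int]]] = []
        self._elig_cache: dict[int, tuple[tuple[int, ...], tuple[float, ...]]] = {}

    def _add_cohort(self, class_key: ClassKey, emerge_year: int, n: int) -> None:
        if n <= 0:
            return
        key = class_key + (emerge_year,)
        if key in self.cohorts:
            self.cohorts[key] += n
        else:
            self.cohorts[key] = n
            heapq.heappush(self._heap, (emerge_year, key))
        self.classes[class_key] = self.classes.get(class_key, 0) + n
        self.count += n
        if self.next_emergence_year is None or emerge_year < self.next_emergence_year:
            self.next_emergence_year = emerge_year

    def add_group(
        self,
        class_key: ClassKey,
        n: int,
        birth_year: int,
        rng: np.random.Generator,
        start_size: float = 0.0,
        start_age: int = 0,
    ) -> None:
        """Add ``n`` identically distributed nymphs born in ``birth_year``,
        splitting them over first-eligible ages by one multinomial draw."""
        if n <= 0:
            return
        if start_size == 0.0 and start_age == 0:
            dist = self._elig_cache.get(class_key[2])
            if dist is None:
                dist = _eligible_age_distribution(self.growth, class_key[2], 0.0, 0)
                self._elig_cache[class_key[2]] = dist
            ages, probs = dist
        else:
            ages, probs = _eligible_age_distribution(
                self.growth, class_key[2], float(start_size), int(start_age)
            )
        if len(ages) == 1:
            self._add_cohort(class_key, birth_year + ages[0], n)
            return
        counts = rng.multinomial(n, probs)
        for age, cnt in zip(ages, counts):
            self._add_cohort(class_key, birth_year + age, int(cnt))

    def collect_emergers(self, year: int) -> dict[ClassKey, int]:
        out: dict[ClassKey, int] = {}
        heap = self._heap
        while heap and heap[0][0] <= year:
            _ey, key = heapq.heappop(heap)
            n = self.cohorts.pop(key, 0)
            if n == 0:
                continue
            ck = key[:3]
            self.count -= n
            remaining = self.classes[ck] - n
            if remaining:
                self.classes[ck] = remaining
            else:
                del self.classes[ck]
            out[ck] = out.get(ck, 0) + n
        self.next_emergence_year = heap[0][0] if heap else None
        return out

    def census(self) -> tuple[int, int, dict[int, int]]:
        het = 0
        phen_counts: dict[int, int] = {}
        for (a_lo, a_hi, phen), n in self.classes.items():
            if a_lo != a_hi:
                het += n
            phen_counts[phen] = phen_counts.get(phen, 0) + n
        return self.count, het, phen_counts

    def class_census(self) -> dict[ClassKey, int]:
        return dict(self.classes)


# --------------------------------------------------------------------------
# individual patch (reference implementation)


class IndividualPatch:
    """Nymph pool as parallel per-individual arrays."""

    __slots__ = ("growth", "a_lo", "a_hi", "phen", "age", "size", "was_ready")

    def __init__(self, growth: GrowthParams):
        self.growth = growth
        self.a_lo = np.empty(0, dtype=np.int64)
        self.a_hi = np.empty(0, dtype=np.int64)
        self.phen = np.empty(0, dtype=np.int64)
        self.age = np.empty(0, dtype=np.int64)
        self.size = np.empty(0, dtype=np.float64)
        self.was_ready = np.empty(0, dtype=bool)

    @property
    def count(self) -> int:
        return self.a_lo.size

    # the cohort engine skips quiet years; the reference engine cannot,
    # so it reports "always possibly emerging"
    @property
    def next_emergence_year(self):
        return -1 if self.count else None

    def _append(self, a_lo, a_hi, phen, age, size, was_ready) -> None:
        self.a_lo = np.concatenate([self.a_lo, a_lo])
        self.a_hi = np.concatenate([self.a_hi, a_hi])
        self.phen = np.concatenate([self.phen, phen])
        self.age = np.concatenate([self.age, age])
        self.size = np.concatenate([self.size, size])
        self.was_ready = np.concatenate([self.was_ready, was_ready])

    def add_founders(self, cycle: int, age: int, n: int) -> None:
        size = expected_size_at_age(age, self.growth)
        self._append(
            np.full(n, cycle, dtype=np.int64),
            np.full(n, cycle, dtype=np.int64),
            np.full(n, cycle, dtype=np.int64),
            np.full(n, age, dtype=np.int64),
            np.full(n, size),
            np.full(n, size >= self.growth.size_threshold, dtype=bool),
        )

    def add_recruits(self, a_lo, a_hi, phen) -> None:
        n = a_lo.size
        self._append(
            a_lo, a_hi, phen,
            np.zeros(n, dtype=np.int64),
            np.zeros(n),
            np.zeros(n, dtype=bool),
        )

    def grow(self, rng: np.random.Generator) -> None:
        g = self.growth
        self.was_ready = self.size >= g.size_threshold
        below = ~self.was_ready
        k = int(below.sum())
        if k:
            if g.sigma == 0.0:
                inc = math.exp(g.mu)
            else:
                inc = rng.lognormal(g.mu, g.sigma, k)
            self.size[below] += inc
        self.age += 1

    def collect_emergers(self, year: int):
        del year  # eligibility is carried entirely by the per-nymph state
        g = self.growth
        age_based = self.phen != SIZE_CODE
        eligible = np.where(
            age_based,
            (self.age >= self.phen) & (self.size >= g.size_threshold),
            self.was_ready,
        )
        if not eligible.any():
            return None
        out = (self.a_lo[eligible], self.a_hi[eligible], self.phen[eligible])
        keep = ~eligible
        self.a_lo = self.a_lo[keep]
        self.a_hi = self.a_hi[keep]
        self.phen = self.phen[keep]
        self.age = self.age[keep]
        self.size = self.size[keep]
        self.was_ready = self.was_ready[keep]
        return out

    def census(self) -> tuple[int, int, dict[int, int]]:
        het = int((self.a_lo != self.a_hi).sum())
        phens, counts = np.unique(self.phen, return_counts=True)
        return self.count, het, {int(p): int(c) for p, c in zip(phens, counts)}

    def class_census(self) -> dict[ClassKey, int]:
        out: dict[ClassKey, int] = {}
        for lo, hi, ph in zip(self.a_lo, self.a_hi, self.phen):
            key = (int(lo), int(hi), int(ph))
            out[key] = out.get(key, 0) + 1
        return out


# --------------------------------------------------------------------------
# state and initialization


@dataclass
class SimulationState:
    config: SimConfig
    mode: str
    rng: np.random.Generator
    patches: list
    founding_cycles: list[int | None]
    year: int = 0
    delay_remaining: int = 0
    events: list[EmergenceEvent] = field(default_factory=list)
    census: list[CensusRecord] = field(default_factory=list)
    delay_starts: list[int] = field(default_factory=list)


def initialize(
    config: SimConfig, rng: np.random.Generator, mode: str = "cohort"
) -> SimulationState:
    """Create the initial population according to the configured scenario."""
    if mode not in ("cohort", "individual"):
        raise ValueError("mode must be 'cohort' or 'individual'")
    groups, labels = _scenario_layout(config, rng)
    patches: list = []
    for patch_groups in groups:
        if mode == "cohort":
            patch = CohortPatch(config.growth)
            for cycle, age, n in patch_groups:
                size = expected_size_at_age(age, config.growth)
                patch.add_group(
                    (cycle, cycle, cycle), n, birth_year=-age, rng=rng,
                    start_size=size, start_age=age,
                )
        else:
            patch = IndividualPatch(config.growth)
            for cycle, age, n in patch_groups:
                patch.add_founders(cycle, age, n)
        patches.append(patch)
    state = SimulationState(
        config=config, mode=mode, rng=rng,
        patches=patches, founding_cycles=list(labels),
    )
    for i, patch in enumerate(patches):
        state.census.append(CensusRecord(0, i, patch.class_census()))
    return state


def sample_father_genotype(adult_pool, rng: np.random.Generator):
    """Uniform draw (with replacement) of a father genotype from a patch's
    post-migration adult pool.

    ``adult_pool`` is either a sequence of genotype keys or a mapping from
    genotype key to count.  Raises on an empty pool: a patch with no adults
    produces no offspring that year.
    """
    if isinstance(adult_pool, dict):
        keys = list(adult_pool)
        counts = np.array([adult_pool[k] for k in keys], dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("empty adult pool")
        return keys[int(rng.choice(len(keys), p=counts / total))]
    if len(adult_pool) == 0:
        raise ValueError("empty adult pool")
    return adult_pool[int(rng.integers(0, len(adult_pool)))]


# --------------------------------------------------------------------------
# cohort-mode phases


def _migrate_cohort(adults, m: float, n_patches: int, rng: np.random.Generator):
    """Binomial/multinomial equivalent of per-adult uniform migration."""
    out: dict[int, dict[ClassKey, int]] = defaultdict(dict)

    def add(i, key, n):
        if n:
            out[i][key] = out[i].get(key, 0) + int(n)

    probs = np.full(n_patches, 1.0 / n_patches)
    for i, pool in adults.items():
        for key, n in pool.items():
            n_mig = int(rng.binomial(n, m))
            add(i, key, n - n_mig)
            if n_mig:
                dest = rng.multinomial(n_mig, probs)
                for j in np.flatnonzero(dest):
                    add(int(j), key, int(dest[j]))
    return {i: pool for i, pool in out.items() if pool}


def _mutate_and_classify(
    pairs: list[tuple[int, int, int]], u: float, rng: np.random.Generator
) -> dict[ClassKey, int]:
    """Offspring classes from (allele, allele, count) triples, applying the
    per-allele mutation and the phenotype resolution (with its random
    rounding) at cohort level.

    Mutation counts per triple come from one vectorized binomial draw with
    the probability ``2u - u^2`` that an offspring carries at least one
    mutated allele; the rare mutants are then resolved one by one.  Random
    rounding of half-integer hybrid phenotypes is aggregated per genotype
    and drawn as a single binomial split.
    """
    newborns: dict[ClassKey, int] = {}
    if not pairs:
        return newborns
    odd: dict[tuple[int, int], int] = {}

    def emit(x: int, y: int, n: int) -> None:
        if n <= 0:
            return
        lo, hi = (x, y) if x <= y else (y, x)
        if lo == SIZE_CODE:
            _bump(newborns, (lo, hi, SIZE_CODE), n)
        elif (lo + hi) % 2 == 0:
            _bump(newborns, (lo, hi, (lo + hi) // 2), n)
        else:
            _bump(odd, (lo, hi), n)

    if u > 0.0:
        p_any = u * (2.0 - u)
        if len(pairs) == 1:
            n_mut = (int(rng.binomial(pairs[0][2], p_any)),) if pairs[0][2] > 0 else (0,)
        else:
            counts = np.fromiter(
                (t[2] for t in pairs), dtype=np.int64, count=len(pairs)
            )
            n_mut = rng.binomial(counts, p_any)
        # conditional mutation pattern of a mutated offspring
        q_first = u * (1.0 - u) / p_any
        q_second = 2.0 * q_first
        for (x, y, n), k in zip(pairs, n_mut):
            emit(x, y, int(n) - int(k))
            for _ in range(int(k)):
                r = rng.random()
                if r < q_first:
                    emit(mutate_allele_code(x, rng), y, 1)
                elif r < q_second:
                    emit(x, mutate_allele_code(y, rng), 1)
                else:
                    emit(mutate_allele_code(x, rng), mutate_allele_code(y, rng), 1)
    else:
        for x, y, n in pairs:
            emit(x, y, n)
    for (lo, hi), n in odd.items():
        up = int(rng.binomial(n, 0.5))
        _bump(newborns, (lo, hi, (lo + hi) // 2 + 1), up)
        _bump(newborns, (lo, hi, (lo + hi) // 2), n - up)
    return newborns


def _emit_one(newborns: dict, x: int, y: int, rng: np.random.Generator) -> None:
    """Classify a single (typically mutated) offspring."""
    lo, hi = (x, y) if x <= y else (y, x)
    if lo == SIZE_CODE:
        _bump(newborns, (lo, hi, SIZE_CODE), 1)
        return
    total = lo + hi
    phen = total // 2
    if total % 2 == 1 and rng.random() < 0.5:
        phen += 1
    _bump(newborns, (lo, hi, phen), 1)


def _reproduce_multi(
    keys: list[tuple[int, int]],
    counts: np.ndarray,
    b: int,
    u: float,
    rng: np.random.Generator,
) -> dict[ClassKey, int]:
    """Offspring classes of a multi-genotype pool, computed with batched
    multinomial/binomial draws end to end.

    One draw each for: father genotype per mother (multinomial broadcast),
    the four allele-transmission combinations per mating pair, the count of
    mutated offspring per transmission class, and the floor/ceil rounding
    split of half-integer hybrid phenotypes.
    """
    probs = counts / counts.sum()
    # father genotype per mother: uniform over adults, with replacement
    fathers = rng.multinomial(counts, probs)  # (k, k)
    mi, fi = np.nonzero(fathers)
    if mi.size == 0:
        return {}
    n_off = fathers[mi, fi] * b
    combos = rng.multinomial(n_off, _QUARTERS)  # (pairs, 4)
    ka = np.asarray(keys, dtype=np.int64)
    x = ka[mi][:, (0, 0, 1, 1)].ravel()
    y = ka[fi][:, (0, 1, 0, 1)].ravel()
    n = combos.ravel()
    nz = n > 0
    x, y, n = x[nz], y[nz], n[nz]
    if u > 0.0:
        p_any = u * (2.0 - u)
        k_mut = rng.binomial(n, p_any)
        n_clean = n - k_mut
    else:
        k_mut = None
        n_clean = n
    lo = np.minimum(x, y)
    hi = np.maximum(x, y)
    total = lo + hi
    size_based = lo == SIZE_CODE
    odd = ~size_based & ((total & 1) == 1)
    phen = np.where(size_based, 0, total >> 1)
    odd_idx = np.flatnonzero(odd)
    ups = rng.binomial(n_clean[odd_idx], 0.5) if odd_idx.size else ()
    newborns: dict[ClassKey, int] = {}
    lo_l, hi_l, phen_l = lo.tolist(), hi.tolist(), phen.tolist()
    n_l, odd_l = n_clean.tolist(), odd.tolist()
    oi = 0
    for t in range(len(n_l)):
        cnt = n_l[t]
        key = (lo_l[t], hi_l[t], phen_l[t])
        if odd_l[t]:
            up = int(ups[oi])
            oi += 1
            if up:
                key_up = (key[0], key[1], key[2] + 1)
                newborns[key_up] = newborns.get(key_up, 0) + up
            cnt -= up
        if cnt:
            newborns[key] = newborns.get(key, 0) + cnt
    if k_mut is not None and k_mut.any():
        q_first = u * (1.0 - u) / p_any
        q_second = 2.0 * q_first
        x_l, y_l = x.tolist(), y.tolist()
        for t in np.flatnonzero(k_mut):
            for _ in range(int(k_mut[t])):
                r = rng.random()
                if r < q_first:
                    _emit_one(newborns, mutate_allele_code(x_l[t], rng), y_l[t], rng)
                elif r < q_second:
                    _emit_one(newborns, x_l[t], mutate_allele_code(y_l[t], rng), rng)
                else:
                    _emit_one(
                        newborns,
                        mutate_allele_code(x_l[t], rng),
                        mutate_allele_code(y_l[t], rng),
                        rng,
                    )
    return newborns


def _bump(d: dict, key, n: int) -> None:
    if n:
        d[key] = d.get(key, 0) + int(n)


_QUARTERS = np.full(4, 0.25)


def _reproduce_cohort(
    pool: dict[ClassKey, int],
    config: SimConfig,
    rng: np.random.Generator,
    mutation_prob: float,
) -> dict[ClassKey, int]:
    """Offspring classes of one patch's adult pool (all adults are females;
    males are assumed present at identical genotype ratios)."""
    b = config.fecundity
    if b == 0 or not pool:
        return {}
    if config.clonal_mode:
        pairs = [(key[0], key[1], n * b) for key, n in pool.items()]
        return _mutate_and_classify(pairs, mutation_prob, rng)
    # mate choice and transmission depend on alleles only, so adult classes
    # that differ just by phenotype (rounding of the same hybrid genotype)
    # are merged before mating
    by_alleles: dict[tuple[int, int], int] = {}
    for (x, y, _phen), n in pool.items():
        key = (x, y)
        by_alleles[key] = by_alleles.get(key, 0) + n
    if len(by_alleles) == 1:
        # single genotype: father genotype is the mother's own
        ((x, y), n), = by_alleles.items()
        n_off = n * b
        if x == y:
            pairs = [(x, x, n_off)]
        else:
            combos = rng.multinomial(n_off, _QUARTERS)
            pairs = [
                (x, x, int(combos[0])), (x, y, int(combos[1])),
                (y, x, int(combos[2])), (y, y, int(combos[3])),
            ]
        return _mutate_and_classify(pairs, mutation_prob, rng)
    keys = list(by_alleles)
    counts = np.array([by_alleles[k] for k in keys], dtype=np.int64)
    return _reproduce_multi(keys, counts, b, mutation_prob, rng)


def _step_cohort(state: SimulationState, year: int, in_burn: bool, p_now: float):
    cfg = state.config
    rng = state.rng
    changed: set[int] = set()
    emergence_allowed = state.delay_remaining == 0
    adults: dict[int, dict[ClassKey, int]] = {}
    if emergence_allowed:
        for i, patch in enumerate(state.patches):
            nxt = patch.next_emergence_year
            if nxt is not None and nxt <= year:
                emergers = patch.collect_emergers(year)
                if emergers:
                    changed.add(i)
                    survivors, event = apply_predation(
                        emergers, cfg.predation, rng,
                        year=year, patch=i, p_override=p_now,
                    )
                    state.events.append(event)
                    if survivors:
                        adults[i] = survivors
    if adults and not in_burn and cfg.migration_prob > 0.0:
        adults = _migrate_cohort(adults, cfg.migration_prob, cfg.n_patches, rng)
    mutation_prob = 0.0 if in_burn else cfg.mutation_prob
    for i, pool in adults.items():
        newborns = _reproduce_cohort(pool, cfg, rng, mutation_prob)
        if not newborns:
            continue
        patch = state.patches[i]
        n0 = sum(newborns.values())
        p_est = establishment_probability(
            RecruitmentInput(N1=patch.count, N0=n0, N=cfg.N)
        )
        for key, n in newborns.items():
            kept = int(rng.binomial(n, p_est)) if p_est < 1.0 else n
            if kept:
                patch.add_group(key, kept, birth_year=year, rng=rng)
                changed.add(i)
    return changed


# --------------------------------------------------------------------------
# individual-mode phases


def _step_individual(state: SimulationState, year: int, in_burn: bool, p_now: float):
    cfg = state.config
    rng = state.rng
    changed: set[int] = set()
    for patch in state.patches:
        patch.grow(rng)
    adults: dict[int, tuple] = {}
    if state.delay_remaining == 0:
        for i, patch in enumerate(state.patches):
            emerged = patch.collect_emergers(year)
            if emerged is None:
                continue
            changed.add(i)
            a_lo, a_hi, phen = emerged
            # predation: one Bernoulli trial per emerging adult
            s = survival_probability(float(a_lo.size), cfg.predation, p_override=p_now)
            keep = rng.random(a_lo.size) < s if s < 1.0 else np.ones(a_lo.size, bool)
            het = a_lo != a_hi
            state.events.append(
                EmergenceEvent(
                    year=year, patch=i, survival_prob=s,
                    hom_emerged=int((~het).sum()),
                    hom_deaths=int((~het & ~keep).sum()),
                    het_emerged=int(het.sum()),
                    het_deaths=int((het & ~keep).sum()),
                )
            )
            if keep.any():
                adults[i] = (a_lo[keep], a_hi[keep], phen[keep])
    if adults and not in_burn and cfg.migration_prob > 0.0:
        pooled: dict[int, list] = defaultdict(list)
        for i, (a_lo, a_hi, phen) in adults.items():
            n = a_lo.size
            dest = np.full(n, i, dtype=np.int64)
            moving = rng.random(n) < cfg.migration_prob
            k = int(moving.sum())
            if k:
                dest[moving] = rng.integers(0, cfg.n_patches, k)
            for j in np.unique(dest):
                sel = dest == j
                pooled[int(j)].append((a_lo[sel], a_hi[sel], phen[sel]))
        adults = {
            j: tuple(np.concatenate(parts) for parts in zip(*chunks))
            for j, chunks in pooled.items()
        }
    mutation_prob = 0.0 if in_burn else cfg.mutation_prob
    for i, (a_lo, a_hi, phen) in adults.items():
        nb = _reproduce_individual(a_lo, a_hi, cfg, rng, mutation_prob)
        if nb is None:
            continue
        nb_lo, nb_hi, nb_phen = nb
        patch = state.patches[i]
        p_est = establishment_probability(
            RecruitmentInput(N1=patch.count, N0=nb_lo.size, N=cfg.N)
        )
        keep = (
            rng.random(nb_lo.size) < p_est
            if p_est < 1.0
            else np.ones(nb_lo.size, bool)
        )
        if keep.any():
            patch.add_recruits(nb_lo[keep], nb_hi[keep], nb_phen[keep])
            changed.add(i)
    return changed


def _reproduce_individual(a_lo, a_hi, cfg: SimConfig, rng, mutation_prob: float):
    """Per-individual mating, transmission, mutation and phenotype rounding."""
    n_adults = a_lo.size
    b = cfg.fecundity
    if n_adults == 0 or b == 0:
        return None
    if cfg.clonal_mode:
        m_allele = np.repeat(a_lo, b)
        f_allele = np.repeat(a_hi, b)
    else:
        fathers = rng.integers(0, n_adults, n_adults)
        mother_idx = np.repeat(np.arange(n_adults), b)
        father_idx = np.repeat(fathers, b)
        m_allele = np.where(
            rng.random(mother_idx.size) < 0.5, a_lo[mother_idx], a_hi[mother_idx]
        )
        f_allele = np.where(
            rng.random(father_idx.size) < 0.5, a_lo[father_idx], a_hi[father_idx]
        )
    if mutation_prob > 0.0:
        for arr in (m_allele, f_allele):
            hits = np.flatnonzero(rng.random(arr.size) < mutation_prob)
            for idx in hits:
                arr[idx] = mutate_allele_code(int(arr[idx]), rng)
    lo = np.minimum(m_allele, f_allele)
    hi = np.maximum(m_allele, f_allele)
    phen = np.zeros(lo.size, dtype=np.int64)
    age_based = lo != SIZE_CODE
    total = lo + hi
    phen[age_based] = total[age_based] // 2
    odd = age_based & (total % 2 == 1)
    k = int(odd.sum())
    if k:
        phen[odd] += (rng.random(k) < 0.5).astype(np.int64)
    return lo, hi, phen


# --------------------------------------------------------------------------
# public loop


def run_year(state: SimulationState) -> SimulationState:
    """Advance the simulation by exactly one year (all eight phases)."""
    cfg = state.config
    year = state.year + 1
    state.year = year
    in_burn = year <= cfg.burn_in_years
    p_now = ramped_predator_density(year, cfg.predation)
    if state.mode == "individual":
        changed = _step_individual(state, year, in_burn, p_now)
    else:
        changed = _step_cohort(state, year, in_burn, p_now)
    record = changed if not cfg.record_every_year else range(len(state.patches))
    for i in sorted(record):
        state.census.append(CensusRecord(year, i, state.patches[i].class_census()))
    # delay-state update: drawn at the end of the year, so a delay starting
    # now blocks years year+1 .. year+d
    if state.delay_remaining > 0:
        state.delay_remaining -= 1
    elif not in_burn and cfg.delays_enabled:
        if state.rng.random() < cfg.p_delay:
            state.delay_remaining = cfg.d
            state.delay_starts.append(year + 1)
    return state


def run_simulation(
    config: SimConfig,
    seed: int | None = None,
    mode: str = "cohort",
) -> RunResult:
    """Burn-in plus main phase; returns the collected records and final state."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    state = initialize(config, rng, mode=mode)
    for _ in range(config.total_years):
        run_year(state)
    return RunResult(
        config=config,
        seed=seed,
        mode=mode,
        years_run=state.year,
        migration_start_year=config.burn_in_years + 1,
        founding_cycles=state.founding_cycles,
        events=state.events,
        census=state.census,
        delay_starts=state.delay_starts,
        final_census={i: p.class_census() for i, p in enumerate(state.patches)},
    )
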