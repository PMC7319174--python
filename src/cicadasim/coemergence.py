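"""Schedule-only coemergence trials.

This module strips away all demography: each cycle length is reduced to its
emergence calendar — the set of calendar years in which a perfectly periodic
population of that cycle would emerge, given a starting age.  Two cycles
*coemerge* when an emergence year is shared.  With a common starting age,
coemergence years of cycles ``ci`` and ``cj`` are exactly the multiples of
``lcm(ci, cj)``, which is what gives prime cycle lengths their rarity of
coemergence; with independent random starting ages that advantage vanishes.

Population-wide emergence delays are overlaid on the calendars: while a
delay of length ``d`` is active no emergence can occur, and any emergence
that would have fallen inside the delay interval happens at the interval's
end instead, after which the cycle continues at its usual period from the
moved year (phase reset).  New delays cannot start during an active delay.
The delay mechanics mirror the full simulation engine exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EmergenceCalendar",
    "DelaySchedule",
    "CoemergenceStats",
    "PRIMES_10_20",
    "build_calendar",
    "generate_delay_schedule",
    "apply_delays",
    "coemergence_proportion",
    "run_trials",
]

#: Prime cycle lengths within the 10..20 competition range.
PRIMES_10_20 = frozenset({11, 13, 17, 19})


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % k for k in range(2, int(math.isqrt(n)) + 1))


@dataclass(frozen=True)
class EmergenceCalendar:
    """Emergence years of one cycle over ``[1, horizon]``."""

    cycle_length: int
    start_age: int
    horizon: int
    emergence_years: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.start_age < self.cycle_length:
            raise ValueError("start_age must be in [0, cycle_length)")


@dataclass(frozen=True)
class DelaySchedule:
    """Non-overlapping delay intervals ``[start, start + d)``.

    ``starts`` lists each delay's first blocked year; emergence blocked
    during a delay happens in year ``start + d``.
    """

    starts: np.ndarray
    d: int
    p_delay: float = 0.0

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts)
        if starts.size and np.any(np.diff(starts) < self.d + 1):
            raise ValueError("delay intervals must not overlap")


@dataclass
class CoemergenceStats:
    """Trial-averaged coemergence statistics for one parameter combination."""

    cycles: tuple[int, ...]
    n_trials: int
    n_trials_with_delay: int
    #: mean proportion of each cycle's emergences shared with another cycle,
    #: over the whole horizon
    per_cycle_proportion: dict[int, float]
    #: same, counting only emergences from the first delay onwards
    #: (trials without a delay excluded); empty when no trial had a delay
    per_cycle_proportion_post_delay: dict[int, float] = field(default_factory=dict)
    #: mean fraction of cycles emerging in the year a delay ends
    sync_fraction: float = float("nan")

    def _diff(self, props: dict[int, float]) -> float:
        nonprime = [v for c, v in props.items() if not _is_prime(c) and not math.isnan(v)]
        prime = [v for c, v in props.items() if _is_prime(c) and not math.isnan(v)]
        if not nonprime or not prime:
            return float("nan")
        return float(np.mean(nonprime) - np.mean(prime))

    @property
    def nonprime_minus_prime(self) -> float:
        """Mean nonprime minus mean prime coemergence proportion, from the
        first delay onwards when delays occurred, otherwise overall."""
        if self.per_cycle_proportion_post_delay:
            return self._diff(self.per_cycle_proportion_post_delay)
        return self._diff(self.per_cycle_proportion)

    @property
    def nonprime_minus_prime_overall(self) -> float:
        return self._diff(self.per_cycle_proportion)


def build_calendar(c: int, start_age: int, horizon: int) -> EmergenceCalendar:
    """Delay-free calendar: emergences at ``c - start_age, 2c - start_age, ...``
    within ``[1, horizon]``."""
    if not 0 <= start_age < c:
        raise ValueError("start_age must be in [0, cycle_length)")
    first = c - start_age
    years = np.arange(first, horizon + 1, c, dtype=np.int64)
    return EmergenceCalendar(c, start_age, horizon, years)


def generate_delay_schedule(
    p_delay: float, d: int, horizon: int, rng: np.random.Generator
) -> DelaySchedule:
    """Draw delay start years with per-year Bernoulli(``p_delay``) suppressed
    during an active delay.

    A success drawn at the end of year ``t`` blocks years ``t+1 .. t+d``;
    draws resume at the end of year ``t+d``, so consecutive starts differ by
    at least ``d + 1``.  Gaps between draw-eligible years are geometric.
    """
    starts: list[int] = []
    if p_delay > 0.0:
        # `draw_from` is the first eligible end-of-year draw; a success after
        # `gap` trials starts blocking the following year
        draw_from = 0
        while True:
            gap = int(rng.geometric(p_delay))  # >= 1
            start = draw_from + gap  # success at end of year start-1
            if start > horizon:
                break
            starts.append(start)
            draw_from = start + d  # draws resume the year the delay ends
    return DelaySchedule(np.asarray(starts, dtype=np.int64), d=d, p_delay=p_delay)


def _delayed_years(cal: EmergenceCalendar, schedule: DelaySchedule) -> np.ndarray:
    c = cal.cycle_length
    horizon = cal.horizon
    next_year = c - cal.start_age
    out: list[np.ndarray] = []
    for s in schedule.starts:
        s = int(s)
        if next_year > horizon:
            break
        end = s + schedule.d
        if next_year < s:
            seg = np.arange(next_year, min(s - 1, horizon) + 1, c, dtype=np.int64)
            out.append(seg)
            next_year = int(seg[-1]) + c
        if next_year >= s and next_year < end:
            # Emergence(s) blocked by this delay happen at its end year, and
            # the cycle's phase resets to the moved year.
            if end <= horizon:
                out.append(np.array([end], dtype=np.int64))
            next_year = end + c
    if next_year <= horizon:
        out.append(np.arange(next_year, horizon + 1, c, dtype=np.int64))
    if not out:
        return np.array([], dtype=np.int64)
    return np.concatenate(out)


def apply_delays(
    calendars: list[EmergenceCalendar], schedule: DelaySchedule
) -> list[EmergenceCalendar]:
    """Reschedule every calendar around the delay intervals, processing
    delays in chronological order so later delays act on moved years."""
    return [
        replace(cal, emergence_years=_delayed_years(cal, schedule))
        for cal in calendars
    ]


def coemergence_proportion(
    calendars: list[EmergenceCalendar],
    focal_cycle: int,
    min_year: int = 1,
) -> float:
    """Fraction of the focal cycle's emergences (in ``[min_year, horizon]``)
    that share their year with at least one other cycle's emergence.

    Returns NaN when the focal cycle has no emergence events in the window.
    """
    focal = [cal for cal in calendars if cal.cycle_length == focal_cycle]
    if len(focal) != 1:
        raise ValueError("exactly one calendar must match the focal cycle")
    horizon = focal[0].horizon
    counts = np.zeros(horizon + 1, dtype=np.int32)
    for cal in calendars:
        years = cal.emergence_years
        counts[years[years >= min_year]] += 1
    years = focal[0].emergence_years
    years = years[years >= min_year]
    if years.size == 0:
        return float("nan")
    return float(np.mean(counts[years] >= 2))


def run_trials(
    cycles: tuple[int, ...],
    n_trials: int,
    horizon: int,
    p_delay: float,
    d: int,
    rng: np.random.Generator,
) -> CoemergenceStats:
    """Monte-Carlo coemergence trials.

    Per trial: draw an independent uniform starting age for every cycle,
    draw a delay schedule, reschedule, and tally (a) each cycle's
    coemergence proportion, (b) the same from the first delay onwards
    (trials without a delay excluded), and (c) the fraction of cycles
    emerging in the year each delay ends.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sums = {c: 0.0 for c in cycles}
    counts = {c: 0 for c in cycles}
    sums_pd = {c: 0.0 for c in cycles}
    counts_pd = {c: 0 for c in cycles}
    sync_sum = 0.0
    sync_count = 0
    trials_with_delay = 0
    for _ in range(n_trials):
        cals = [build_calendar(c, int(rng.integers(0, c)), horizon) for c in cycles]
        schedule = generate_delay_schedule(p_delay, d, horizon, rng)
        if schedule.starts.size:
            cals = apply_delays(cals, schedule)
            trials_with_delay += 1
        year_counts = np.zeros(horizon + 1, dtype=np.int32)
        for cal in cals:
            year_counts[cal.emergence_years] += 1
        first_delay = int(schedule.starts[0]) if schedule.starts.size else None
        for cal in cals:
            years = cal.emergence_years
            if years.size:
                sums[cal.cycle_length] += float(np.mean(year_counts[years] >= 2))
                counts[cal.cycle_length] += 1
            if first_delay is not None:
                post = years[years >= first_delay]
                if post.size:
                    sums_pd[cal.cycle_length] += float(np.mean(year_counts[post] >= 2))
                    counts_pd[cal.cycle_length] += 1
        if schedule.starts.size:
            ends = schedule.starts + d
            ends = ends[ends <= horizon]
            if ends.size:
                # fraction of cycles emerging in each delay's end year
                sync_sum += float(np.sum(year_counts[ends])) / len(cycles)
                sync_count += ends.size

    per_cycle = {
        c: (sums[c] / counts[c] if counts[c] else float("nan")) for c in cycles
    }
    per_cycle_pd = (
        {c: (sums_pd[c] / counts_pd[c] if counts_pd[c] else float("nan")) for c in cycles}
        if trials_with_delay
        else {}
    )
    return CoemergenceStats(
        cycles=tuple(cycles),
        n_trials=n_trials,
        n_trials_with_delay=trials_with_delay,
        per_cycle_proportion=per_cycle,
        per_cycle_proportion_post_delay=per_cycle_pd,
        sync_fraction=(sync_sum / sync_count if sync_count else float("nan")),
    )
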