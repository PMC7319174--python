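"""Scenario metrics, replicate aggregation, fixtures and file I/O.

The quantities computed here summarize full simulation runs: the fraction
of individuals carrying a prime-numbered phenotype cycle, time-averaged
heterozygote proportions per patch, predation mortality split by genotype
class (the homozygote/heterozygote contrast that drives selection against
hybrids), and detection of a patch being invaded by a cycle other than its
founder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coemergence import _is_prime, build_calendar
from .config import SimConfig, load_config
from .engine import CensusRecord, RunResult, run_simulation
from .genetics import SIZE_CODE
from .predation import EmergenceEvent

__all__ = [
    "RunSummary",
    "prime_proportion",
    "phenotype_census",
    "heterozygote_proportion",
    "mortality_by_class",
    "invasion_detector",
    "patch_windows",
    "summarize_run",
    "replicate_seeds",
    "run_replicates",
    "mean_prime_proportion",
    "pooled_mortality",
    "ReplicateStats",
    "collect_replicate_stats",
    "stats_prime_proportion",
    "stats_mortality",
    "make_fixture",
    "events_frame",
    "census_frame",
    "write_frame",
    "read_frame",
    "summary_to_json",
]


# --------------------------------------------------------------------------
# core metrics


def prime_proportion(census: dict[int, int]) -> float:
    """Fraction of individuals whose phenotype cycle length is prime.

    ``census`` maps phenotype code to count; the size-based phenotype
    (code 0) counts as nonprime.  An empty census is undefined (NaN).
    """
    total = sum(census.values())
    if total == 0:
        return float("nan")
    prime = sum(n for phen, n in census.items() if phen != SIZE_CODE and _is_prime(phen))
    return prime / total


def phenotype_census(final_census: dict) -> dict[int, int]:
    """Merge a per-patch class census into phenotype counts."""
    out: dict[int, int] = {}
    for patch_classes in final_census.values():
        for (_lo, _hi, phen), n in patch_classes.items():
            out[phen] = out.get(phen, 0) + n
    return out


def _segments(records: list[CensusRecord], end_year: int):
    """Yield (first_year, last_year, record) spans of constant composition."""
    for rec, nxt in zip(records, records[1:] + [None]):
        last = end_year if nxt is None else nxt.year - 1
        if last >= rec.year:
            yield rec.year, last, rec


def heterozygote_proportion(
    records: list[CensusRecord], window: tuple[int, int]
) -> float:
    """Time-averaged heterozygote fraction of one patch over ``window``
    (inclusive years); patch-years with no individuals are excluded."""
    start, end = window
    acc = 0.0
    years = 0
    for seg_start, seg_last, rec in _segments(records, end):
        lo = max(seg_start, start)
        hi = min(seg_last, end)
        total = rec.total
        if hi >= lo and total > 0:
            w = hi - lo + 1
            acc += w * rec.het / total
            years += w
    return acc / years if years else float("nan")


def mortality_by_class(
    events: list[EmergenceEvent],
    windows: dict[int, tuple[int, int]] | None = None,
) -> tuple[float, float]:
    """Predation mortality per genotype class: total deaths over total
    emergence size, for homozygotes and heterozygotes.

    ``windows`` optionally restricts events to a per-patch year window;
    patches absent from the mapping contribute nothing.  A class with no
    emergence in the window is reported as NaN.
    """
    hom_e = hom_d = het_e = het_d = 0
    for ev in events:
        if windows is not None:
            win = windows.get(ev.patch)
            if win is None or not win[0] <= ev.year <= win[1]:
                continue
        hom_e += ev.hom_emerged
        hom_d += ev.hom_deaths
        het_e += ev.het_emerged
        het_d += ev.het_deaths
    hom = hom_d / hom_e if hom_e else float("nan")
    het = het_d / het_e if het_e else float("nan")
    return hom, het


def invasion_detector(
    records: list[CensusRecord], founding_cycle: int | None
) -> int | None:
    """First year in which the patch's most common phenotype cycle is not the
    founding cycle (strictly more common: ties count as held), or ``None``."""
    if founding_cycle is None:
        return None
    for rec in records:
        counts = rec.phen_counts
        resident = counts.get(founding_cycle, 0)
        if any(n > resident for phen, n in counts.items() if phen != founding_cycle):
            return rec.year
    return None


def patch_windows(
    result: RunResult, from_first_delay: bool = False
) -> dict[int, tuple[int, int]]:
    """Measurement window per patch: from migration onset (or from the first
    emergence delay) until the patch is invaded or the run ends."""
    if from_first_delay:
        if not result.delay_starts:
            return {}
        start = result.delay_starts[0]
    else:
        start = result.migration_start_year
    by_patch: dict[int, list[CensusRecord]] = {}
    for rec in result.census:
        by_patch.setdefault(rec.patch, []).append(rec)
    windows = {}
    for patch, records in by_patch.items():
        founding = result.founding_cycles[patch]
        invaded = invasion_detector(records, founding)
        end = result.years_run if invaded is None else invaded
        if end >= start:
            windows[patch] = (start, end)
    return windows


# --------------------------------------------------------------------------
# run summaries and replicate aggregation


@dataclass
class RunSummary:
    scenario: str
    seed: int | None
    years_run: int
    final_phenotype_census: dict[int, int]
    final_census: dict[int, dict] = field(repr=False)
    prime_proportion: float = float("nan")
    patches_retained: int = 0
    fixated: bool = False
    hom_mortality: float = float("nan")
    het_mortality: float = float("nan")
    het_proportion_by_patch: dict[int, float] = field(default_factory=dict)
    n_delays: int = 0


def summarize_run(result: RunResult, from_first_delay: bool = False) -> RunSummary:
    """Collapse one run into its headline metrics.

    ``from_first_delay`` switches the mortality/heterozygosity window from
    "migration onset -> invasion" to "first delay -> invasion", the
    measurement used when emergence delays are part of the scenario.
    """
    phen_census = phenotype_census(result.final_census)
    total = sum(phen_census.values())
    dominant = max(phen_census.values()) if phen_census else 0
    windows = patch_windows(result, from_first_delay=from_first_delay)
    hom, het = mortality_by_class(result.events, windows)
    by_patch: dict[int, list[CensusRecord]] = {}
    for rec in result.census:
        by_patch.setdefault(rec.patch, []).append(rec)
    het_props = {
        patch: heterozygote_proportion(by_patch.get(patch, []), win)
        for patch, win in windows.items()
    }
    retained = 0
    for patch, classes in result.final_census.items():
        founding = result.founding_cycles[patch]
        if founding is None:
            continue
        counts: dict[int, int] = {}
        for (_lo, _hi, phen), n in classes.items():
            counts[phen] = counts.get(phen, 0) + n
        resident = counts.get(founding, 0)
        if all(n <= resident for phen, n in counts.items() if phen != founding):
            retained += 1
    return RunSummary(
        scenario=result.config.scenario,
        seed=result.seed,
        years_run=result.years_run,
        final_phenotype_census=phen_census,
        final_census=result.final_census,
        prime_proportion=prime_proportion(phen_census),
        patches_retained=retained,
        fixated=(total > 0 and dominant / total >= 0.99),
        hom_mortality=hom,
        het_mortality=het,
        het_proportion_by_patch=het_props,
        n_delays=len(result.delay_starts),
    )


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Fixed per-replicate seeds derived from the master seed and index."""
    return [
        int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0] % 2**31)
        for i in range(n)
    ]


def run_replicates(
    config: SimConfig, master_seed: int, n_replicates: int, mode: str = "cohort"
) -> list[RunResult]:
    return [
        run_simulation(config, seed=s, mode=mode)
        for s in replicate_seeds(master_seed, n_replicates)
    ]


def mean_prime_proportion(results: list[RunResult]) -> tuple[float, float]:
    """Mean and standard error (over replicates) of the final prime-cycle
    proportion."""
    props = np.array(
        [prime_proportion(phenotype_census(r.final_census)) for r in results]
    )
    props = props[~np.isnan(props)]
    if props.size == 0:
        return float("nan"), float("nan")
    se = props.std(ddof=1) / np.sqrt(props.size) if props.size > 1 else float("nan")
    return float(props.mean()), float(se)


def _window_tallies(result: RunResult, windows) -> tuple[int, int, int, int]:
    hom_e = hom_d = het_e = het_d = 0
    for ev in result.events:
        win = windows.get(ev.patch)
        if win is None or not win[0] <= ev.year <= win[1]:
            continue
        hom_e += ev.hom_emerged
        hom_d += ev.hom_deaths
        het_e += ev.het_emerged
        het_d += ev.het_deaths
    return hom_e, hom_d, het_e, het_d


def pooled_mortality(
    results: list[RunResult], from_first_delay: bool = False
) -> tuple[float, float]:
    """Per-class mortality pooled over all replicates' measurement windows
    (total deaths over total emergence size per class)."""
    hom_e = hom_d = het_e = het_d = 0
    for result in results:
        windows = patch_windows(result, from_first_delay=from_first_delay)
        e, d, he, hd = _window_tallies(result, windows)
        hom_e += e
        hom_d += d
        het_e += he
        het_d += hd
    hom = hom_d / hom_e if hom_e else float("nan")
    het = het_d / het_e if het_e else float("nan")
    return hom, het


@dataclass
class ReplicateStats:
    """Lightweight per-replicate aggregates for large batch experiments.

    Full ``RunResult`` objects hold every emergence event and census change
    of a run; for multi-replicate experiments those records are reduced to
    the handful of numbers the analyses need so replicates can be streamed
    without holding all runs in memory.
    """

    seed: int
    prime_proportion: float
    patches_retained: int
    fixated: bool
    n_delays: int
    hom_emerged: int
    hom_deaths: int
    het_emerged: int
    het_deaths: int


def collect_replicate_stats(
    config: SimConfig,
    master_seed: int,
    n_replicates: int,
    from_first_delay: bool = False,
    mode: str = "cohort",
) -> list[ReplicateStats]:
    """Run replicates one at a time and keep only their summary statistics.

    Mortality tallies are restricted to the per-patch measurement windows
    (migration onset, or the first delay when ``from_first_delay``, up to
    invasion or the end of the run).
    """
    out = []
    for seed in replicate_seeds(master_seed, n_replicates):
        result = run_simulation(config, seed=seed, mode=mode)
        windows = patch_windows(result, from_first_delay=from_first_delay)
        hom_e, hom_d, het_e, het_d = _window_tallies(result, windows)
        phen_census = phenotype_census(result.final_census)
        total = sum(phen_census.values())
        dominant = max(phen_census.values()) if phen_census else 0
        summary_retained = 0
        for patch, classes in result.final_census.items():
            founding = result.founding_cycles[patch]
            if founding is None:
                continue
            counts: dict[int, int] = {}
            for (_lo, _hi, phen), count in classes.items():
                counts[phen] = counts.get(phen, 0) + count
            resident = counts.get(founding, 0)
            if all(n <= resident for p, n in counts.items() if p != founding):
                summary_retained += 1
        out.append(
            ReplicateStats(
                seed=seed,
                prime_proportion=prime_proportion(phen_census),
                patches_retained=summary_retained,
                fixated=(total > 0 and dominant / total >= 0.99),
                n_delays=len(result.delay_starts),
                hom_emerged=hom_e,
                hom_deaths=hom_d,
                het_emerged=het_e,
                het_deaths=het_d,
            )
        )
        del result
    return out


def stats_prime_proportion(stats: list[ReplicateStats]) -> tuple[float, float]:
    """Mean and standard error of the final prime-cycle proportion."""
    props = np.array([s.prime_proportion for s in stats])
    props = props[~np.isnan(props)]
    if props.size == 0:
        return float("nan"), float("nan")
    se = props.std(ddof=1) / np.sqrt(props.size) if props.size > 1 else float("nan")
    return float(props.mean()), float(se)


def stats_mortality(stats: list[ReplicateStats]) -> tuple[float, float]:
    """Pooled per-class mortality across streamed replicates."""
    hom_e = sum(s.hom_emerged for s in stats)
    hom_d = sum(s.hom_deaths for s in stats)
    het_e = sum(s.het_emerged for s in stats)
    het_d = sum(s.het_deaths for s in stats)
    hom = hom_d / hom_e if hom_e else float("nan")
    het = het_d / het_e if het_e else float("nan")
    return hom, het


# --------------------------------------------------------------------------
# fixtures


def make_fixture(name: str, seed: int = 0):
    """Small deterministic fixtures for tests and examples.

    ``two_patch_13_17``
        SimConfig: two patches founded by 13- and 17-year homozygotes at
        reduced scale (N=2000, short burn-in, 2000 main years).
    ``single_patch_13``
        SimConfig: one isolated 13-year patch, no predators, no migration
        or mutation (deterministic periodicity checks).
    ``calendar_2_3``
        The two toy emergence calendars with cycles 2 and 3 over a 12-year
        horizon and zero starting ages.
    """
    if name == "two_patch_13_17":
        return load_config(
            n_patches=2,
            cycle_lengths=[13, 17],
            scenario="random_ages",
            burn_in_years=200,
            main_years=2000,
            N=2000,
            predation={"ramp_years": 100},
            seed=seed,
        )
    if name == "single_patch_13":
        return load_config(
            n_patches=1,
            cycle_lengths=[13],
            scenario="newborn_start",
            burn_in_years=0,
            main_years=60,
            N=2000,
            migration_prob=0.0,
            mutation_prob=0.0,
            predation={"p": 0.0},
            seed=seed,
        )
    if name == "calendar_2_3":
        return [build_calendar(2, 0, 12), build_calendar(3, 0, 12)]
    raise ValueError(f"unknown fixture {name!r}")


# --------------------------------------------------------------------------
# file I/O


def events_frame(results: list[RunResult]) -> pd.DataFrame:
    """Tidy emergence-event table over replicates (one row per patch-year
    emergence, with per-class emergence sizes and deaths)."""
    rows = []
    for rep, result in enumerate(results):
        delay_ends = {s + result.config.d for s in result.delay_starts}
        for ev in result.events:
            rows.append(
                {
                    "replicate": rep,
                    "year": ev.year,
                    "patch": ev.patch,
                    "survival_prob": ev.survival_prob,
                    "hom_emerged": ev.hom_emerged,
                    "hom_deaths": ev.hom_deaths,
                    "het_emerged": ev.het_emerged,
                    "het_deaths": ev.het_deaths,
                    "delayed_flag": ev.year in delay_ends,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate", "year", "patch", "survival_prob",
            "hom_emerged", "hom_deaths", "het_emerged", "het_deaths",
            "delayed_flag",
        ],
    )


def census_frame(results: list[RunResult]) -> pd.DataFrame:
    """Tidy census table: one row per (replicate, change-year, patch,
    phenotype cycle, genotype class)."""
    rows = []
    for rep, result in enumerate(results):
        for rec in result.census:
            grouped: dict[tuple[int, str], int] = {}
            for (lo, hi, phen), n in rec.class_counts.items():
                key = (phen, "het" if lo != hi else "hom")
                grouped[key] = grouped.get(key, 0) + n
            for (phen, cls), n in sorted(grouped.items()):
                rows.append(
                    {
                        "replicate": rep,
                        "year": rec.year,
                        "patch": rec.patch,
                        "phenotype_cycle": phen,
                        "genotype_class": cls,
                        "count": n,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate", "year", "patch", "phenotype_cycle",
            "genotype_class", "count",
        ],
    )


def write_frame(frame: pd.DataFrame, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(path, index=False, float_format="%.17g")


def read_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def _phen_label(code: int) -> str:
    return "SIZE" if code == SIZE_CODE else f"AGE:{code}"


def summary_to_json(summary: RunSummary, path=None) -> str:
    """Serialize a run summary; genotype classes become readable strings."""
    doc = {
        "scenario": summary.scenario,
        "seed": summary.seed,
        "years_run": summary.years_run,
        "prime_proportion": summary.prime_proportion,
        "patches_retained": summary.patches_retained,
        "fixated": summary.fixated,
        "hom_mortality": summary.hom_mortality,
        "het_mortality": summary.het_mortality,
        "n_delays": summary.n_delays,
        "final_phenotype_census": {
            _phen_label(p): n for p, n in sorted(summary.final_phenotype_census.items())
        },
        "het_proportion_by_patch": {
            str(k): v for k, v in sorted(summary.het_proportion_by_patch.items())
        },
        "final_census": {
            str(patch): {
                f"{_phen_label(lo)}|{_phen_label(hi)}|phen={_phen_label(phen)}": n
                for (lo, hi, phen), n in sorted(classes.items())
            }
            for patch, classes in summary.final_census.items()
        },
    }
    text = json.dumps(_nan_to_none(doc), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _nan_to_none(obj):
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_nan_to_none(v) for v in obj]
    return obj
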