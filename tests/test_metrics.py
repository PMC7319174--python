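"""Run summaries, per-class mortality, invasion detection, I/O round-trips."""

import json
import math

import numpy as np
import pytest

from cicadasim.config import load_config
from cicadasim.engine import CensusRecord, run_simulation
from cicadasim.metrics import (
    census_frame,
    events_frame,
    heterozygote_proportion,
    invasion_detector,
    make_fixture,
    mean_prime_proportion,
    mortality_by_class,
    phenotype_census,
    prime_proportion,
    read_frame,
    replicate_seeds,
    run_replicates,
    summarize_run,
    summary_to_json,
    write_frame,
)
from cicadasim.predation import EmergenceEvent


class TestPrimeProportion:
    def test_equal_counts_over_10_to_20(self):
        census = {c: 100 for c in range(10, 21)}
        assert prime_proportion(census) == pytest.approx(4 / 11)

    def test_all_prime(self):
        assert prime_proportion({13: 500}) == 1.0

    def test_all_nonprime(self):
        assert prime_proportion({12: 500}) == 0.0

    def test_size_phenotype_counts_as_nonprime(self):
        assert prime_proportion({0: 50, 13: 50}) == 0.5

    def test_empty_census_undefined(self):
        assert math.isnan(prime_proportion({}))

    def test_merged_census_is_weighted_mean_of_patches(self):
        """Prime proportion of a merged census equals the count-weighted mean
        of per-patch proportions."""
        patches = {
            0: {(13, 13, 13): 300},
            1: {(12, 12, 12): 100, (11, 11, 11): 100},
            2: {(14, 15, 14): 50, (17, 17, 17): 150},
        }
        merged = prime_proportion(phenotype_census(patches))
        per_patch = []
        weights = []
        for classes in patches.values():
            census = {}
            for (_l, _h, p), n in classes.items():
                census[p] = census.get(p, 0) + n
            per_patch.append(prime_proportion(census))
            weights.append(sum(classes.values()))
        assert merged == pytest.approx(np.average(per_patch, weights=weights))


class TestHeterozygoteProportion:
    def _records(self):
        return [
            CensusRecord(0, 0, {(13, 13, 13): 100}),
            CensusRecord(10, 0, {(13, 13, 13): 50, (13, 17, 15): 50}),
            CensusRecord(20, 0, {}),
            CensusRecord(30, 0, {(13, 13, 13): 80, (13, 17, 15): 20}),
        ]

    def test_pure_homozygote_patch(self):
        records = [CensusRecord(0, 0, {(13, 13, 13): 10})]
        assert heterozygote_proportion(records, (0, 100)) == 0.0

    def test_direct_count(self):
        records = [CensusRecord(0, 0, {(13, 13, 13): 50, (13, 17, 15): 50})]
        assert heterozygote_proportion(records, (0, 10)) == pytest.approx(0.5)

    def test_time_weighting_and_empty_years_excluded(self):
        # years 0-9: 0.0 (10y); 10-19: 0.5 (10y); 20-29 empty (excluded);
        # 30-39: 0.2 (10y)
        got = heterozygote_proportion(self._records(), (0, 39))
        assert got == pytest.approx((10 * 0.0 + 10 * 0.5 + 10 * 0.2) / 30)

    def test_window_restriction(self):
        got = heterozygote_proportion(self._records(), (10, 19))
        assert got == pytest.approx(0.5)

    def test_all_empty_window_is_nan(self):
        assert math.isnan(heterozygote_proportion(self._records(), (20, 29)))


class TestMortalityByClass:
    def _events(self):
        return [
            EmergenceEvent(5, 0, 0.9, hom_emerged=100, hom_deaths=10),
            EmergenceEvent(9, 0, 0.5, hom_emerged=100, hom_deaths=30,
                           het_emerged=50, het_deaths=40),
            EmergenceEvent(30, 1, 0.6, hom_emerged=100, hom_deaths=40),
        ]

    def test_single_event_ratio(self):
        events = [EmergenceEvent(1, 0, 0.6, hom_emerged=100, hom_deaths=40)]
        hom, het = mortality_by_class(events)
        assert hom == pytest.approx(0.40)
        assert math.isnan(het)  # class absent

    def test_zero_mortality(self):
        events = [EmergenceEvent(1, 0, 1.0, hom_emerged=10, het_emerged=5)]
        assert mortality_by_class(events) == (0.0, 0.0)

    def test_pooled_over_events(self):
        hom, het = mortality_by_class(self._events())
        assert hom == pytest.approx(80 / 300)
        assert het == pytest.approx(40 / 50)

    def test_window_filtering(self):
        windows = {0: (0, 6)}  # patch 1 excluded entirely
        hom, het = mortality_by_class(self._events(), windows)
        assert hom == pytest.approx(10 / 100)
        assert math.isnan(het)


class TestInvasionDetector:
    def test_stable_resident(self):
        records = [CensusRecord(y, 0, {(13, 13, 13): 99, (12, 13, 12): 1})
                   for y in (0, 50, 100)]
        assert invasion_detector(records, 13) is None

    def test_constructed_flip_detected(self):
        records = [
            CensusRecord(0, 0, {(13, 13, 13): 90}),
            CensusRecord(100, 0, {(13, 13, 13): 40, (17, 17, 17): 60}),
        ]
        assert invasion_detector(records, 13) == 100

    def test_tie_counts_as_held(self):
        records = [CensusRecord(10, 0, {(13, 13, 13): 50, (17, 17, 17): 50})]
        assert invasion_detector(records, 13) is None

    def test_unlabelled_patch_is_ignored(self):
        records = [CensusRecord(0, 0, {(17, 17, 17): 10})]
        assert invasion_detector(records, None) is None


class TestFixtures:
    def test_two_patch_fixture(self):
        cfg = make_fixture("two_patch_13_17")
        assert cfg.cycle_lengths == (13, 17)
        assert cfg.n_patches == 2

    def test_calendar_fixture(self):
        cals = make_fixture("calendar_2_3")
        assert [c.cycle_length for c in cals] == [2, 3]

    def test_fixture_determinism(self):
        a = make_fixture("two_patch_13_17", seed=5)
        b = make_fixture("two_patch_13_17", seed=5)
        assert a == b

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("no_such_fixture")


class TestReplicates:
    def test_seeds_deterministic_and_bounded(self):
        seeds = replicate_seeds(42, 8)
        assert seeds == replicate_seeds(42, 8)
        assert len(set(seeds)) == 8
        assert all(0 <= s < 2**31 for s in seeds)

    def test_mean_prime_proportion_reports_se(self):
        cfg = load_config(
            n_patches=2, cycle_lengths=[13, 16], scenario="random_ages",
            burn_in_years=30, main_years=40, N=100,
            predation={"p": 1.0, "a": 1.0, "h": 1.0, "ramp_years": 10},
        )
        results = run_replicates(cfg, 7, 3)
        mean, se = mean_prime_proportion(results)
        assert 0.0 <= mean <= 1.0
        assert se >= 0.0


@pytest.fixture(scope="module")
def small_result():
    cfg = load_config(
        n_patches=2, cycle_lengths=[13, 17], scenario="random_ages",
        burn_in_years=100, main_years=300, N=500,
        predation={"p": 3.0, "a": 1.0, "h": 0.5, "ramp_years": 50},
        seed=1,
    )
    return run_simulation(cfg, seed=1)


class TestIO:
    def test_events_frame_round_trip(self, small_result, tmp_path):
        frame = events_frame([small_result])
        path = tmp_path / "events.csv"
        write_frame(frame, path)
        back = read_frame(path)
        assert back.equals(frame)

    def test_census_frame_round_trip(self, small_result, tmp_path):
        frame = census_frame([small_result])
        path = tmp_path / "census.csv"
        write_frame(frame, path)
        back = read_frame(path)
        assert back.equals(frame)

    def test_summary_json_serialization(self, small_result, tmp_path):
        summary = summarize_run(small_result)
        path = tmp_path / "summary.json"
        text = summary_to_json(summary, path)
        doc = json.loads(path.read_text())
        assert doc == json.loads(text)
        assert doc["scenario"] == "random_ages"
        assert all(k.startswith(("AGE:", "SIZE"))
                   for k in doc["final_phenotype_census"])
        assert 0.0 <= doc["prime_proportion"] <= 1.0

    def test_summary_counts_match_result(self, small_result):
        summary = summarize_run(small_result)
        assert sum(summary.final_phenotype_census.values()) == sum(
            sum(c.values()) for c in small_result.final_census.values()
        )
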