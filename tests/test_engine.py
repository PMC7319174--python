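"""Yearly loop: phase order, scenarios, delays, reproducibility, and the
distributional equivalence of the cohort and per-individual engines."""

import numpy as np
import pytest
from scipy import stats

from cicadasim import load_config, run_simulation
from cicadasim.engine import initialize, run_year, sample_father_genotype
from cicadasim.metrics import make_fixture, summarize_run


def small_config(**overrides):
    base = dict(
        n_patches=3,
        cycle_lengths=[12, 13, 17],
        scenario="random_ages",
        burn_in_years=50,
        main_years=150,
        N=200,
        predation={"p": 3.0, "a": 1.0, "h": 0.5, "ramp_years": 25},
        seed=0,
    )
    base.update(overrides)
    return load_config(**base)


class TestInitialization:
    def test_newborn_start_all_age_zero(self, rng):
        cfg = small_config(scenario="newborn_start")
        state = initialize(cfg, rng, mode="individual")
        for patch in state.patches:
            assert np.all(patch.age == 0)
            assert np.all(patch.size == 0.0)

    def test_random_ages_one_shared_age_per_patch(self, rng):
        cfg = small_config(scenario="random_ages")
        state = initialize(cfg, rng, mode="individual")
        for patch, c in zip(state.patches, cfg.cycle_lengths):
            ages = np.unique(patch.age)
            assert ages.size == 1
            assert 0 <= ages[0] < c

    def test_twenty_patch_random_layout(self, rng):
        cfg = load_config(
            scenario="twenty_patch_random", n_patches=20,
            burn_in_years=10, main_years=10, N=100,
        )
        state = initialize(cfg, rng)
        assert len(state.patches) == 20
        assert all(c in cfg.cycle_lengths for c in state.founding_cycles)

    def test_single_patch_mixes_all_cycles(self, rng):
        cfg = load_config(
            scenario="single_patch", n_patches=1,
            burn_in_years=10, main_years=10, N=1100,
        )
        state = initialize(cfg, rng)
        census = state.patches[0].class_census()
        assert {key[2] for key in census} == set(cfg.cycle_lengths)

    def test_duplicate_cycles_rejected(self):
        with pytest.raises(ValueError):
            small_config(cycle_lengths=[13, 13, 17])

    def test_initial_fill(self, rng):
        cfg = small_config()
        state = initialize(cfg, rng)
        assert all(p.count == round(0.9 * cfg.N) for p in state.patches)


class TestPeriodicity:
    @pytest.mark.parametrize("mode", ["cohort", "individual"])
    def test_isolated_patch_emerges_on_cycle(self, mode):
        """A pure 13-year patch with no predators emerges exactly in years
        13, 26, 39, ... — periodicity is preserved."""
        cfg = make_fixture("single_patch_13")
        result = run_simulation(cfg, seed=3, mode=mode)
        years = sorted({ev.year for ev in result.events})
        assert years == [13, 26, 39, 52]
        assert all(ev.deaths == 0 for ev in result.events)

    def test_burn_in_only_run_keeps_founding_cycles(self):
        cfg = small_config(main_years=0)
        result = run_simulation(cfg, seed=5)
        for patch, c in zip(result.final_census.values(), cfg.cycle_lengths):
            assert {key[2] for key in patch} == {c}


class TestDelays:
    def test_active_delay_blocks_emergence(self, rng):
        cfg = make_fixture("single_patch_13")
        state = initialize(cfg, np.random.default_rng(1))
        for _ in range(12):
            run_year(state)
        state.delay_remaining = 3
        run_year(state)  # year 13: the cohort is eligible but blocked
        assert state.events == []
        run_year(state)
        run_year(state)
        assert state.events == []
        run_year(state)  # delay expired: everyone emerges now
        assert len(state.events) == 1 and state.events[0].year == 16

    def test_no_delays_during_burn_in(self):
        cfg = small_config(p_delay=1.0, d=5, scenario="random_ages_with_delays",
                           burn_in_years=60, main_years=0)
        result = run_simulation(cfg, seed=2)
        assert result.delay_starts == []

    def test_delay_starts_are_spaced_by_full_length(self):
        cfg = small_config(p_delay=1.0, d=5, scenario="random_ages_with_delays",
                           burn_in_years=20, main_years=60)
        result = run_simulation(cfg, seed=2)
        gaps = np.diff(result.delay_starts)
        assert len(result.delay_starts) > 0
        assert np.all(gaps == 6)  # d blocked years + the emergence year


class TestEvolutionInvariants:
    def test_allele_set_never_grows_without_mutation(self):
        cfg = small_config(mutation_prob=0.0, main_years=300)
        result = run_simulation(cfg, seed=9)
        alleles = set()
        for census in result.final_census.values():
            for (lo, hi, _p) in census:
                alleles |= {lo, hi}
        assert alleles <= set(cfg.cycle_lengths)

    def test_migration_off_keeps_patches_independent(self):
        cfg = small_config(migration_prob=0.0, mutation_prob=0.0, main_years=300)
        result = run_simulation(cfg, seed=4)
        for patch, c in zip(result.final_census.values(), cfg.cycle_lengths):
            assert all(key == (c, c, c) for key in patch)

    def test_clonal_mode_copies_mother_genotype(self):
        cfg = small_config(clonal=True, mutation_prob=0.0, main_years=300)
        result = run_simulation(cfg, seed=6)
        for census in result.final_census.values():
            for (lo, hi, _p) in census:
                assert lo == hi  # founders are homozygous; clones stay so

    def test_adults_never_persist_across_years(self):
        """Total nymph count just after a year equals the recorded census;
        emergence events never appear in consecutive years for an isolated
        periodic patch (adults die within their emergence year)."""
        cfg = make_fixture("single_patch_13")
        result = run_simulation(cfg, seed=8)
        years = sorted(ev.year for ev in result.events)
        assert all(b - a == 13 for a, b in zip(years, years[1:]))


class TestReproducibility:
    @pytest.mark.parametrize("mode", ["cohort", "individual"])
    def test_same_seed_bit_identical_logs(self, mode):
        cfg = small_config()
        r1 = run_simulation(cfg, seed=123, mode=mode)
        r2 = run_simulation(cfg, seed=123, mode=mode)
        assert [
            (e.year, e.patch, e.hom_emerged, e.hom_deaths, e.het_emerged, e.het_deaths)
            for e in r1.events
        ] == [
            (e.year, e.patch, e.hom_emerged, e.hom_deaths, e.het_emerged, e.het_deaths)
            for e in r2.events
        ]
        assert r1.final_census == r2.final_census
        assert [
            (c.year, c.patch, c.class_counts) for c in r1.census
        ] == [(c.year, c.patch, c.class_counts) for c in r2.census]

    def test_different_seeds_differ(self):
        cfg = small_config()
        r1 = run_simulation(cfg, seed=1)
        r2 = run_simulation(cfg, seed=2)
        assert r1.final_census != r2.final_census


class TestFatherSampling:
    def test_uniform_pool(self, rng):
        pool = {(13, 13, 13): 50, (17, 17, 17): 50}
        n = 10_000
        draws = [sample_father_genotype(pool, rng) for _ in range(n)]
        count = sum(1 for d in draws if d == (13, 13, 13))
        assert abs(count - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_single_class_pool_is_certain(self, rng):
        pool = {(13, 13, 13): 7}
        assert all(
            sample_father_genotype(pool, rng) == (13, 13, 13) for _ in range(20)
        )

    def test_empty_pool_raises(self, rng):
        with pytest.raises(ValueError):
            sample_father_genotype({}, rng)
        with pytest.raises(ValueError):
            sample_father_genotype([], rng)


class TestHybridMortalityMechanism:
    def test_heterozygotes_predated_more_than_homozygotes(self):
        """In the two-patch 13/17 system with migration, hybrid emergers are
        out of phase with both parent cohorts, emerge in small numbers and
        suffer far heavier predation."""
        cfg = make_fixture("two_patch_13_17")
        result = run_simulation(cfg, seed=10)
        summary = summarize_run(result)
        assert summary.het_mortality > summary.hom_mortality


class TestEngineEquivalence:
    def test_cohort_and_individual_engines_match(self):
        """The cohort-aggregated engine is distributionally equivalent to the
        naive per-individual engine: replicate distributions of total
        emergence and of final population size are indistinguishable
        (two-sample KS, alpha 0.01, Bonferroni-corrected)."""
        cfg = small_config(main_years=150)
        n_reps = 200
        samples = {}
        for mode in ("cohort", "individual"):
            emerged = np.empty(n_reps)
            final_pop = np.empty(n_reps)
            for rep in range(n_reps):
                r = run_simulation(cfg, seed=50_000 + rep, mode=mode)
                emerged[rep] = sum(ev.emerged for ev in r.events)
                final_pop[rep] = sum(
                    sum(c.values()) for c in r.final_census.values()
                )
            samples[mode] = (emerged, final_pop)
        n_tests = 2
        for i in range(n_tests):
            ks = stats.ks_2samp(samples["cohort"][i], samples["individual"][i])
            assert ks.pvalue > 0.01 / n_tests
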