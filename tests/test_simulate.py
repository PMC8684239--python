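"""Trial-simulation engine: accrual, event times, administrative censoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parsurvsim import (
    ScenarioConfig,
    apply_administrative_censoring,
    build_dataset_grid,
    censor_time_for_proportion,
    draw_sample,
    generate_population,
    scenario_preset,
)


class TestScenarioConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"lambda12": -0.1},
            {"lambda12": 0.0},
            {"t1_max": 0.5},
            {"pe_levels": (0.5, 0.2, 1.0)},  # not increasing
            {"pe_levels": (0.2, 0.5)},  # last != 1
            {"n_obs_levels": (60, 30)},
            {"n_obs_levels": (30, 60), "pop_size": 50},
            {"n_sim": 0},
            {"truth_source": "oracle"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ScenarioConfig(**kw)

    def test_presets_cover_accrual_by_rate_grid(self):
        combos = {
            (scenario_preset(s).t1_max, scenario_preset(s).lambda12)
            for s in (1, 2, 3, 4)
        }
        assert combos == {
            (270, 0.0025), (900, 0.0025), (270, 0.00075), (900, 0.00075)
        }

    def test_yaml_round_trip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        assert ScenarioConfig.from_yaml(p) == small_config
        assert ScenarioConfig.from_yaml(p, seed=99).seed == 99
        p.write_text("lambda12: 0.001\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            ScenarioConfig.from_yaml(p)


class TestGeneratePopulation:
    @pytest.mark.parametrize(
        "rate,expected_median", [(0.0025, 277.26), (0.00075, 924.20)]
    )
    def test_event_time_median_matches_theory(self, rate, expected_median):
        cfg = ScenarioConfig(lambda12=rate, pop_size=50_000, seed=5)
        pop = generate_population(cfg)
        # MC error of the median of 50k exponentials is ~ median/sqrt(n)
        tol = 3 * expected_median / math.sqrt(50_000)
        assert np.median(pop.event_times) == pytest.approx(
            expected_median, abs=tol
        )

    def test_enrollment_uniform_on_accrual_window(self):
        cfg = scenario_preset(1, seed=5)
        pop = generate_population(cfg)
        assert pop.enroll_times.min() >= 1.0
        assert pop.enroll_times.max() <= 270.0
        assert np.mean(pop.enroll_times) == pytest.approx(135.5, rel=0.02)

    def test_same_seed_bit_identical(self):
        cfg = scenario_preset(1, seed=11, pop_size=1000)
        a, b = generate_population(cfg), generate_population(cfg)
        assert np.array_equal(a.enroll_times, b.enroll_times)
        assert np.array_equal(a.event_times, b.event_times)

    def test_calendar_bookkeeping(self):
        cfg = scenario_preset(1, seed=2, pop_size=500)
        pop = generate_population(cfg)
        assert pop.max_event_calendar_time == np.max(
            pop.enroll_times + pop.event_times
        )


class TestDrawSample:
    def test_exhaustive_when_n_equals_population(self, rng):
        cfg = ScenarioConfig(pop_size=600, n_obs_levels=(600,), seed=1)
        pop = generate_population(cfg)
        idx = draw_sample(pop, 600, rng)
        assert sorted(idx) == list(range(600))

    def test_without_replacement_and_reproducible(self, scenario1_population):
        idx = draw_sample(
            scenario1_population, 30, np.random.default_rng(3)
        )
        assert len(set(idx)) == 30
        idx2 = draw_sample(
            scenario1_population, 30, np.random.default_rng(3)
        )
        assert np.array_equal(idx, idx2)

    def test_oversized_sample_rejected(self, rng):
        cfg = ScenarioConfig(pop_size=100, n_obs_levels=(100,), seed=1)
        pop = generate_population(cfg)
        with pytest.raises(ValueError):
            draw_sample(pop, 101, rng)


class TestCensoring:
    def test_censor_time_is_rank_order_statistic(self):
        enr = np.array([1.0, 1.0, 1.0])
        ev = np.array([10.0, 20.0, 30.0])
        assert censor_time_for_proportion(enr, ev, 2 / 3) == 21.0
        assert censor_time_for_proportion(enr, ev, 1.0) == 31.0

    def test_decile_rank_uses_ceiling(self):
        # 10% of 30 -> the 3rd calendar event
        enr = np.zeros(30) + 1.0
        ev = np.arange(1.0, 31.0)
        assert censor_time_for_proportion(enr, ev, 0.1) == 1.0 + 3.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            censor_time_for_proportion(np.array([]), np.array([]), 0.5)

    def test_truncation_rule(self):
        enr = np.array([1.0, 1.0, 1.0])
        ev = np.array([10.0, 20.0, 30.0])
        ds = apply_administrative_censoring(enr, ev, 21.0)
        assert np.allclose(ds.times, [10.0, 20.0, 20.0])
        assert list(ds.events) == [1, 1, 0]

    def test_complete_followup_observes_everything(self):
        enr = np.array([5.0, 7.0])
        ev = np.array([100.0, 3.0])
        ds = apply_administrative_censoring(enr, ev, 105.0)
        assert ds.n_events == 2

    def test_not_yet_enrolled_excluded(self):
        enr = np.array([1.0, 25.0])
        ev = np.array([10.0, 50.0])
        ds = apply_administrative_censoring(enr, ev, 21.0)
        assert ds.n == 1
        assert ds.times[0] == 10.0

    def test_cut_before_all_enrollment_rejected(self):
        with pytest.raises(ValueError):
            apply_administrative_censoring(
                np.array([30.0, 40.0]), np.array([1.0, 1.0]), 21.0
            )

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_censoring_monotone_in_event_proportion(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 40))
        enr = r.uniform(1, 270, n)
        ev = r.exponential(400, n)
        prev = None
        for pe in (0.2, 0.5, 0.8, 1.0):
            c = censor_time_for_proportion(enr, ev, pe)
            ds = apply_administrative_censoring(enr, ev, c + 1e-9)
            follow = {}
            kept = enr < c + 1e-9
            for i, (t, e) in zip(np.nonzero(kept)[0], zip(ds.times, ds.events)):
                follow[i] = (t, e)
            if prev is not None:
                for i, (t, e) in prev.items():
                    t2, e2 = follow[i]
                    assert t2 >= t - 1e-9  # follow-up never shrinks
                    if e:  # an observed event stays observed
                        assert e2 == 1 and t2 == pytest.approx(t)
            prev = follow


class TestDatasetGrid:
    def test_grid_size_and_grouping_tags(self, small_config):
        pop = generate_population(small_config)
        grid = list(build_dataset_grid(pop, small_config))
        assert len(grid) == small_config.n_datasets == 3 * 2 * 2
        assert {(d.rep, d.n_obs, d.pe) for d in grid} == {
            (r, n, p)
            for r in range(3)
            for n in (30, 60)
            for p in (0.5, 1.0)
        }

    def test_event_counts_match_ceiling_rule(self, small_config):
        pop = generate_population(small_config)
        for ds in build_dataset_grid(pop, small_config):
            # continuous times: the cut sits exactly at the r-th event
            assert ds.n_events == math.ceil(ds.pe * ds.n_obs)
            if ds.pe == 1.0:
                assert ds.n_events == ds.n_obs == ds.n

    def test_nested_censoring_within_repetition(self, small_config):
        pop = generate_population(small_config)
        grid = list(build_dataset_grid(pop, small_config))
        by_key = {(d.rep, d.n_obs, d.pe): d for d in grid}
        for rep in range(3):
            for n_obs in (30, 60):
                short = by_key[(rep, n_obs, 0.5)]
                full = by_key[(rep, n_obs, 1.0)]
                short_events = sorted(
                    short.times[short.events.astype(bool)]
                )
                full_events = sorted(full.times[full.events.astype(bool)])
                # events observed early are a subset of the complete data
                for t in short_events:
                    assert any(np.isclose(t, u) for u in full_events)

    def test_full_grid_reproducible(self, small_config):
        pop = generate_population(small_config)
        g1 = list(build_dataset_grid(pop, small_config))
        g2 = list(build_dataset_grid(pop, small_config))
        assert all(
            np.array_equal(a.times, b.times)
            and np.array_equal(a.events, b.events)
            for a, b in zip(g1, g2)
        )

    def test_km_median_of_complete_large_sample(self, scenario1_population):
        """Nonparametric check: KM median of a complete sample ~ -ln(.5)/rate."""
        from lifelines import KaplanMeierFitter

        cfg = scenario_preset(1, seed=123, n_sim=1, n_obs_levels=(500,))
        ds = list(build_dataset_grid(scenario1_population, cfg))[-1]
        assert ds.pe == 1.0
        km = KaplanMeierFitter().fit(ds.times, ds.events)
        assert km.median_survival_time_ == pytest.approx(
            277.26, rel=3 / np.sqrt(500)
        )
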