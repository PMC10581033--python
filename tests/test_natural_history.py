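"""Unit and statistical tests of the natural-history engine."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

import crcscreen.natural_history as nh
from crcscreen import LifeTable, simulate_person_unscreened
from crcscreen.params import ConfigError


def _flat_life_table(q_before: float = 0.0, final_age: int = 100) -> LifeTable:
    ages = tuple(range(final_age + 1))
    q = tuple([q_before] * final_age + [1.0])
    return LifeTable(ages=ages, q_female=q, q_male=q)


class TestOtherCauseDeath:
    def test_certain_death_in_first_year(self, rng):
        lt = LifeTable(ages=(0,), q_female=(1.0,), q_male=(1.0,))
        for _ in range(20):
            a = nh.draw_other_cause_death("female", lt, rng)
            assert 0.0 <= a < 1.0

    def test_death_only_in_final_bucket(self, rng):
        lt = _flat_life_table(0.0, 100)
        for _ in range(20):
            a = nh.draw_other_cause_death("male", lt, rng)
            assert 100.0 <= a < 101.0

    def test_mean_matches_closed_form(self, bundle, rng):
        lt = bundle.life_table
        draws = np.array([nh.draw_other_cause_death("female", lt, rng)
                          for _ in range(100_000)])
        expect = lt.expected_death_age("female")
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expect) < 3 * se

    def test_start_age_conditions_on_survival(self, bundle, rng):
        lt = bundle.life_table
        draws = [nh.draw_other_cause_death("male", lt, rng, start_age=65)
                 for _ in range(200)]
        assert min(draws) >= 65.0

    def test_start_age_outside_table_rejected(self, bundle, rng):
        with pytest.raises(ConfigError):
            nh.draw_other_cause_death("male", bundle.life_table, rng,
                                      start_age=500)


class TestAdenomaOnsets:
    def test_zero_rate_gives_no_onsets(self, bundle, rng):
        p = replace(bundle.nh_params, baseline_log_onset_rate=-math.inf)
        for _ in range(10):
            assert nh.draw_adenoma_onsets("male", 1.0, p, 80.0, rng) == []

    def test_negative_frailty_rejected(self, bundle, rng):
        with pytest.raises(ConfigError):
            nh.draw_adenoma_onsets("male", -0.5, bundle.nh_params, 80.0, rng)

    def test_constant_rate_poisson_mean(self, bundle, rng):
        # single age band => homogeneous Poisson with rate exp(log-rate)
        lam, T = 0.05, 40.0
        p = replace(bundle.nh_params, baseline_log_onset_rate=math.log(lam),
                    sex_effect_male=0.0, age_band_edges=(0.0,),
                    age_band_effects=(0.0,), frailty_sd=0.0)
        counts = np.array([len(nh.draw_adenoma_onsets("female", 1.0, p, T, rng))
                           for _ in range(100_000)])
        expect = lam * T
        se = math.sqrt(expect / len(counts))  # Poisson variance = mean
        assert abs(counts.mean() - expect) < 3 * se

    def test_constant_rate_count_distribution_poisson(self, bundle, rng):
        from scipy import stats
        lam, T, n = 0.08, 25.0, 100_000
        p = replace(bundle.nh_params, baseline_log_onset_rate=math.log(lam),
                    sex_effect_male=0.0, age_band_edges=(0.0,),
                    age_band_effects=(0.0,), frailty_sd=0.0)
        counts = np.array([len(nh.draw_adenoma_onsets("female", 1.0, p, T, rng))
                           for _ in range(n)])
        mu = lam * T
        kmax = int(stats.poisson.ppf(0.9999, mu))
        obs = np.bincount(np.minimum(counts, kmax + 1),
                          minlength=kmax + 2).astype(float)
        pk = stats.poisson.pmf(np.arange(kmax + 1), mu)
        expected = np.append(pk, 1.0 - pk.sum()) * n
        keep = expected > 5
        chi2 = float(((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum())
        crit = stats.chi2.ppf(0.999, keep.sum() - 1)
        assert chi2 < crit

    def test_piecewise_rate_matches_numeric_integration(self, bundle, rng):
        from scipy.integrate import quad
        p = replace(bundle.nh_params, baseline_log_onset_rate=-3.0,
                    sex_effect_male=0.25,
                    age_band_edges=(0.0, 20.0, 45.0, 60.0),
                    age_band_effects=(0.2, 0.9, 1.4, 0.6), frailty_sd=0.0)
        T = 70.0
        intensity = lambda a: math.exp(p.onset_log_rate(a, "male"))
        expect = sum(quad(intensity, a0, a1)[0]
                     for a0, a1 in [(0, 20), (20, 45), (45, 60), (60, T)])
        counts = np.array([len(nh.draw_adenoma_onsets("male", 1.0, p, T, rng))
                           for _ in range(50_000)])
        se = math.sqrt(expect / len(counts))
        assert abs(counts.mean() - expect) < 3 * se

    def test_onsets_sorted_and_within_horizon(self, bundle, rng):
        for _ in range(50):
            ons = nh.draw_adenoma_onsets("male", 2.0, bundle.nh_params, 77.3, rng)
            ages = [a for a, _ in ons]
            assert ages == sorted(ages)
            assert all(0 < a <= 77.3 for a in ages)


class TestLesionGrowth:
    def lesion(self, t10=12.0):
        return nh.Lesion(onset_age=50.0, location="distal_colon",
                         time_to_10mm=t10)

    def test_size_at_onset_is_initial_diameter(self, bundle):
        assert nh.lesion_size_at(self.lesion(), 50.0,
                                 bundle.nh_params) == pytest.approx(1.0)

    def test_reaches_10mm_at_drawn_time(self, bundle):
        assert nh.lesion_size_at(self.lesion(12.0), 62.0,
                                 bundle.nh_params) == pytest.approx(10.0)

    def test_monotone_over_age_grid(self, bundle):
        les = self.lesion(9.0)
        ages = np.linspace(50.0, 100.0, 100)
        sizes = [nh.lesion_size_at(les, a, bundle.nh_params) for a in ages]
        assert all(s1 >= s0 for s0, s1 in zip(sizes, sizes[1:]))
        assert max(sizes) <= bundle.nh_params.max_diameter_mm

    def test_query_before_onset_rejected(self, bundle):
        with pytest.raises(ValueError):
            nh.lesion_size_at(self.lesion(), 49.9, bundle.nh_params)


class TestTransition:
    def test_probability_zero_never_transitions(self, bundle, rng):
        p = replace(bundle.nh_params, transition_intercept=-math.inf)
        les = nh.Lesion(onset_age=40.0, location="rectum", time_to_10mm=10.0)
        assert all(nh.draw_transition(les, "male", p, 100.0, rng) is None
                   for _ in range(50))

    def test_probability_one_transitions_within_first_year(self, bundle, rng):
        p = replace(bundle.nh_params, transition_intercept=math.inf)
        les = nh.Lesion(onset_age=40.0, location="rectum", time_to_10mm=10.0)
        for _ in range(50):
            t = nh.draw_transition(les, "male", p, 100.0, rng)
            assert t is not None and 40.0 < t < 41.0

    def test_constant_probability_geometric_mean(self, bundle, rng):
        # flat annual probability p: waiting time is geometric-like with
        # mean ~ 1/p years for small p
        p_annual = 0.05
        logit = math.log(p_annual / (1 - p_annual))
        p = replace(bundle.nh_params, transition_intercept=logit,
                    transition_per_mm=0.0, transition_per_year_age=0.0,
                    transition_male=0.0)
        les = nh.Lesion(onset_age=0.0, location="rectum", time_to_10mm=10.0)
        waits = []
        for _ in range(100_000):
            t = nh.draw_transition(les, "female", p, 1e9, rng)
            waits.append(t)
        waits = np.asarray(waits, dtype=float)
        # geometric(p) years-to-success + U(0,1) placement
        expect = 1.0 / p_annual - 0.5
        se = waits.std(ddof=1) / math.sqrt(len(waits))
        assert abs(waits.mean() - expect) < 3 * se


class TestSojournAndStage:
    def test_degenerate_sojourn(self, bundle, rng):
        p = replace(bundle.nh_params,
                    sojourn_lognormal={"colon": {"mu": math.log(2.0), "sigma": 0.0},
                                       "rectum": {"mu": math.log(2.0), "sigma": 0.0}})
        s, _ = nh.draw_sojourn_and_stage("distal_colon", p, rng)
        assert s == pytest.approx(2.0)

    def test_stage_path_ends_at_symptomatic_stage(self, bundle, rng):
        for _ in range(100):
            soj, stage = nh.draw_sojourn_and_stage("rectum", bundle.nh_params, rng)
            pc = nh.PreclinicalCancer(lesion_index=0, onset_age=60.0,
                                      sojourn_time=soj, location="rectum",
                                      symptomatic_stage=stage,
                                      survival_quantile=0.5)
            assert nh.stage_at(pc, 60.0 + soj) == stage

    def test_stage_path_non_decreasing(self, bundle):
        pc = nh.PreclinicalCancer(lesion_index=0, onset_age=60.0,
                                  sojourn_time=4.0, location="rectum",
                                  symptomatic_stage=4, survival_quantile=0.5)
        stages = [nh.stage_at(pc, a) for a in np.linspace(60.0, 64.0, 200)]
        assert stages[0] == 1 and stages[-1] == 4
        assert all(b >= a for a, b in zip(stages, stages[1:]))

    def test_symptomatic_stage_distribution(self, bundle, rng):
        n = 100_000
        draws = np.array([nh.draw_sojourn_and_stage("rectum", bundle.nh_params,
                                                    rng)[1]
                          for _ in range(n)])
        for stage, p in zip((1, 2, 3, 4), bundle.nh_params.stage_probs):
            frac = (draws == stage).mean()
            se = math.sqrt(p * (1 - p) / n)
            assert abs(frac - p) < 3 * se


class TestSurvival:
    def test_survival_function_matches_closed_form(self, bundle, rng):
        params = bundle.nh_params
        draws = np.array([nh.draw_crc_survival(2, "colon", "female", 70.0,
                                               params, rng)
                          for _ in range(100_000)])
        scale = params.survival_scale(2, "colon", "female", 70.0)
        for t in (1.0, 3.0, 8.0, 20.0):
            s_true = math.exp(-(t / scale) ** params.survival_shape)
            emp = (draws > t).mean()
            se = math.sqrt(s_true * (1 - s_true) / len(draws))
            assert abs(emp - s_true) < 4 * se

    def test_stage_one_dominates_stage_four(self, bundle, rng):
        params = bundle.nh_params
        # identical quantile coupling: dominance holds pathwise
        for u in np.linspace(0.01, 0.99, 25):
            t1 = nh.weibull_survival_time(u, 1, "colon", "male", 66.0, params)
            t4 = nh.weibull_survival_time(u, 4, "colon", "male", 66.0, params)
            assert t1 >= t4

    def test_extreme_hazard_limit(self, bundle):
        params = replace(bundle.nh_params,
                         survival_scale_by_stage=(1e-9, 1e-9, 1e-9, 1e-9))
        t = nh.weibull_survival_time(0.5, 4, "colon", "male", 66.0, params)
        assert t < 1e-6

    def test_missing_stratum_rejected(self, bundle, rng):
        with pytest.raises(ConfigError):
            nh.draw_crc_survival(5, "colon", "male", 66.0, bundle.nh_params, rng)


class TestWholePerson:
    def test_zero_adenoma_rate_dies_of_other_causes(self, bundle):
        p = replace(bundle.nh_params, baseline_log_onset_rate=-math.inf)
        person = simulate_person_unscreened((3, 0, 0), p, bundle.life_table)
        assert person.death_cause == "other"
        assert person.cancers == [] and person.lesions == []
        assert person.death_age == person.other_cause_death_age

    def test_same_seed_is_bit_identical(self, bundle):
        a = simulate_person_unscreened((11, 42, 0), bundle.nh_params,
                                       bundle.life_table)
        b = simulate_person_unscreened((11, 42, 0), bundle.nh_params,
                                       bundle.life_table)
        assert a == b

    def test_event_ordering_and_no_post_mortem_events(self, bundle):
        for i in range(400):
            p = simulate_person_unscreened((5, i, 0), bundle.nh_params,
                                           bundle.life_table)
            assert p.death_age <= p.other_cause_death_age or \
                p.death_cause != "other"
            for les in p.lesions:
                assert 0 < les.onset_age <= p.other_cause_death_age
                if les.transition_age is not None:
                    assert les.transition_age > les.onset_age
            for pc in p.preclinical:
                assert pc.onset_age < pc.clinical_age
            for c in p.cancers:
                assert c.detection_age <= p.death_age
                assert c.survival_time > 0
            if p.death_cause == "crc":
                c = p.cancers[0]
                assert p.death_age == pytest.approx(
                    c.detection_age + c.survival_time)
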