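import math
import random

import numpy as np
import pytest

from htnsim.care_process import (MedicationRegimen, STRATEGY_PRESETS,
                                 adherence_at, apply_adherence, apply_titration,
                                 bp_goal, get_strategy, intensify_decision,
                                 measure_bp, measurement_sd, next_visit_time,
                                 process_params, BPMeasurement)
from htnsim.config import ConfigurationError


class TestGoals:
    def test_jnc7_conditional_goal(self):
        s = get_strategy("jnc7_usual")
        assert bp_goal(s, {"ckd": 0, "diabetes": 0}) == (140.0, 90.0)
        assert bp_goal(s, {"ckd": 1, "diabetes": 0}) == (130.0, 80.0)
        # diabetes developing mid-simulation tightens the goal thereafter
        assert bp_goal(s, {"ckd": 0, "diabetes": 1}) == (130.0, 80.0)

    def test_fixed_goals(self):
        assert bp_goal(get_strategy("sprint_intensive"), {}) == (120.0, 90.0)
        assert bp_goal(get_strategy("accaha_usual"), {}) == (130.0, 80.0)
        assert bp_goal(get_strategy("tbc"), {}) == (130.0, 80.0)

    def test_unknown_strategy_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            get_strategy("nonexistent")


class TestVisitSchedule:
    def test_sprint_protocol_monthly_then_quarterly(self, values):
        s = get_strategy("sprint_intensive")
        t, kind = next_visit_time(s, {"controlled": False}, 0.0, values)
        assert (t, kind) == (pytest.approx(1 / 12), "physician")
        assert next_visit_time(s, {}, 1 / 12, values)[0] == pytest.approx(2 / 12)
        assert next_visit_time(s, {}, 2 / 12, values)[0] == pytest.approx(3 / 12)
        assert next_visit_time(s, {}, 3 / 12, values)[0] == pytest.approx(6 / 12)
        assert next_visit_time(s, {}, 3.0, values)[0] == pytest.approx(3.25)

    def test_tbc_six_week_grid_through_year_one(self, values):
        s = get_strategy("tbc")
        t = 0.0
        nonphys = []
        while True:
            t, kind = next_visit_time(s, {"controlled": True}, t, values)
            if not math.isfinite(t) or t > 1.05:
                break
            if kind == "nonphysician":
                nonphys.append(t)
        expected = [k * 6 / 52 for k in range(1, 9) if k * 6 / 52 <= 1.0 + 1e-9]
        assert np.allclose(nonphys, expected)

    def test_post_intervention_schedule_reverts_to_usual(self, values):
        """After the protocol window the schedule equals the usual-care rule."""
        sprint, usual = get_strategy("sprint_intensive"), get_strategy("jnc7_usual")
        for controlled in (True, False):
            state = {"controlled": controlled}
            assert (next_visit_time(sprint, state, 3.27, values)
                    == next_visit_time(usual, state, 3.27, values))

    def test_usual_interval_depends_on_control(self, values):
        s = get_strategy("jnc7_usual")
        t_unc, _ = next_visit_time(s, {"controlled": False}, 1.0, values)
        t_con, _ = next_visit_time(s, {"controlled": True}, 1.0, values)
        assert t_unc < t_con

    def test_past_horizon_returns_sentinel(self, values):
        s = get_strategy("jnc7_usual")
        assert next_visit_time(s, {"controlled": True}, 9.9, values,
                               horizon=10.0) == (math.inf, None)

    def test_process_params_revert_exactly_after_intervention(self, values):
        for name in ("sprint_intensive", "tbc"):
            s = get_strategy(name)
            after = s.intervention_duration + 0.01
            assert process_params(s, after, values, "physician") == (
                values["p_intensify_usual"], values["readings_per_visit_usual"])
            assert adherence_at(s, after, values) == values["adherence_usual"]


class TestMeasurement:
    def test_noiseless_limit(self, values):
        v = dict(values, sigma_base_mmhg=0.0, sigma_floor_mmhg=0.0)
        m = measure_bp(137.0, 82.0, 1, 0, random.Random(0), v)
        assert (m.measured_sbp, m.measured_dbp) == (137.0, 82.0)

    def test_unbiased(self, values):
        rng = random.Random(1)
        xs = [measure_bp(140.0, 80.0, 1, 0, rng, values).measured_sbp
              for _ in range(10_000)]
        sd = measurement_sd(1, 0, values)
        assert abs(np.mean(xs) - 140.0) < 4 * sd / np.sqrt(10_000)

    def test_sd_scales_with_readings(self, values):
        """Empirical SD ratio for 4 vs 1 readings ~ 1/2 (no floor, no decay)."""
        v = dict(values, sigma_floor_mmhg=0.0, sigma_visit_decay=0.0)
        rng = random.Random(2)
        sd1 = np.std([measure_bp(140, 80, 1, 0, rng, v).measured_sbp
                      for _ in range(8000)])
        sd4 = np.std([measure_bp(140, 80, 4, 0, rng, v).measured_sbp
                      for _ in range(8000)])
        assert sd4 / sd1 == pytest.approx(0.5, abs=0.05)

    def test_sd_shrinks_with_accumulated_visits_to_floor(self, values):
        sds = [measurement_sd(1, n, values) for n in (0, 5, 50, 10_000)]
        assert all(a >= b for a, b in zip(sds, sds[1:]))
        assert sds[-1] == pytest.approx(values["sigma_floor_mmhg"], abs=1e-6)

    def test_negative_sigma_rejected(self, values):
        with pytest.raises(ConfigurationError):
            measurement_sd(1, 0, dict(values, sigma_base_mmhg=-1.0))


class TestIntensification:
    def test_never_intensify_below_goal(self):
        m = BPMeasurement(118.0, 70.0, 5.0)
        assert not intensify_decision(m, (120.0, 90.0), 1.0, random.Random(0))

    def test_degenerate_probability_one(self):
        m = BPMeasurement(125.0, 70.0, 5.0)
        assert intensify_decision(m, (120.0, 90.0), 1.0, random.Random(0))

    def test_dbp_alone_can_trigger(self):
        m = BPMeasurement(118.0, 95.0, 5.0)
        assert intensify_decision(m, (120.0, 90.0), 1.0, random.Random(0))

    def test_empirical_frequency_matches_probability(self):
        rng = random.Random(3)
        m = BPMeasurement(150.0, 95.0, 5.0)
        p = 0.35
        hits = sum(intensify_decision(m, (140, 90), p, rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / 10_000))


class TestTitration:
    def test_dose_up_before_new_med(self):
        r = MedicationRegimen(n_meds=1, total_steps=1, baseline_steps=0,
                              max_meds=5, steps_per_med=2)
        r2 = apply_titration(r)
        assert (r2.n_meds, r2.total_steps) == (1, 2)   # full dose first
        r3 = apply_titration(r2)
        assert (r3.n_meds, r3.total_steps) == (2, 3)   # then a new agent

    def test_saturation_is_absorbing(self):
        r = MedicationRegimen(5, 10, 0, max_meds=5, steps_per_med=2)
        assert apply_titration(r) == r

    def test_exhaustive_titration_from_zero(self):
        """steps_per_med * max_meds titrations fill the regimen exactly."""
        r = MedicationRegimen.at_baseline(0, max_meds=5, steps_per_med=2)
        for _ in range(10):
            r = apply_titration(r)
        assert (r.n_meds, r.total_steps) == (5, 10)
        assert r.saturated

    def test_baseline_meds_enter_at_full_dose(self):
        r = MedicationRegimen.at_baseline(3, max_meds=5, steps_per_med=4)
        assert r.total_steps == 12
        assert r.added_steps == 0


@pytest.mark.parametrize("effect,adh,expected", [(10.0, 1.0, 10.0),
                                                 (10.0, 0.0, 0.0),
                                                 (10.0, 0.8, 8.0)])
def test_adherence_scales_effect(effect, adh, expected):
    assert apply_adherence(effect, adh) == pytest.approx(expected)


def test_adherence_out_of_range_rejected():
    with pytest.raises(ConfigurationError):
        apply_adherence(10.0, 1.2)
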