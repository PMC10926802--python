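import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from htnsim.care_process import get_strategy
from htnsim.des_core import (CohortSim, EVENT_PRIORITY, records_to_dataframe,
                             select_next)
from htnsim.population import TRAJ_AGES, Cohort

# terminal records: explicit death kinds or a fatal CVD/SAE event record
DEATH_KINDS = {"cvd_death", "non_cvd_death"}
FATAL_EVENT_KINDS = {"chd", "stroke", "hf", "sae"}


def make_flat_cohort(n=1, age=60.0, female=1, n_meds=0, clinical_cvd=0,
                     sbp=140.0, dbp=85.0):
    """Cohort with constant (flat) trajectories for engine-oracle tests."""
    df = pd.DataFrame({
        "id": np.arange(n), "traj_row": np.arange(n),
        "baseline_age": float(age), "female": female, "race_black": 0,
        "smoker": 0, "sbp": float(sbp), "dbp": float(dbp), "bmi": 25.0,
        "hdl": 50.0, "ldl": 110.0, "egfr": 80.0, "diabetes": 0,
        "clinical_cvd": clinical_cvd, "ckd": 0, "n_meds": n_meds,
        "diabetes_onset_age": 999.0, "weight": 1.0,
    })
    base = {"sbp": sbp, "dbp": dbp, "bmi": 25.0, "hdl": 50.0, "ldl": 110.0,
            "egfr": 80.0}
    traj = {f: np.full((n, len(TRAJ_AGES)), v) for f, v in base.items()}
    return Cohort(df, traj)


def toy_values(values, *, chd=0.0, stroke=0.0, hf=0.0, noncvd=0.0, sae=0.0,
               iae=0.0, cf=0.0, noshow=1.0):
    """Constant hazards across ages/sexes, covariate effects off, care off."""
    v = dict(values)
    zero = {"smoker": 0, "sbp_per10": 0, "bmi_per5": 0, "diabetes": 0,
            "hdl_per10": 0, "ldl_per10": 0, "ckd": 0, "race_black": 0}
    for outcome, rate in (("chd", chd), ("stroke", stroke), ("hf", hf),
                          ("noncvd_death", noncvd)):
        v[f"h0_{outcome}_female"] = [rate] * 5
        v[f"h0_{outcome}_male"] = [rate] * 5
        if outcome != "noncvd_death":
            v[f"coef_{outcome}"] = dict(zero)
    v["coef_noncvd_death"] = dict(zero)
    v["cvd_hazard_scale"] = 1.0
    v["sae_rate_by_meds"] = [sae] * 6
    v["iae_rate_by_meds"] = [iae] * 6
    v["sae_rate_scale"] = v["iae_rate_scale"] = 1.0
    v["recurrent_cvd_female"] = v["recurrent_cvd_male"] = [0.0] * 5
    v["chronic_cvd_death_female"] = v["chronic_cvd_death_male"] = [0.0] * 5
    v["acute_cf_by_age"] = [cf] * 5
    v["acute_cf_scale"] = 1.0
    v["fatal_sae_prob_by_age"] = [0.0] * 5
    v["noshow_prob"] = noshow
    return v


class TestSelectNext:
    def test_minimum_time_wins(self):
        assert select_next([(0.25, "physician_visit"), (0.30, "chd")]) == \
            (0.25, "physician_visit")

    def test_exact_tie_breaks_by_priority(self):
        assert select_next([(1.0, "physician_visit"), (1.0, "non_cvd_death")]) == \
            (1.0, "non_cvd_death")
        assert select_next([(1.0, "sae"), (1.0, "stroke")]) == (1.0, "stroke")

    def test_empty_candidates_is_internal_error(self):
        with pytest.raises(RuntimeError):
            select_next([])


class TestDegenerateRuns:
    def test_no_hazards_no_visits_gives_single_horizon_record(self, values):
        cohort = make_flat_cohort()
        sim = CohortSim(cohort, toy_values(values), horizon_years=10.0)
        r = sim.run_individual(0, get_strategy("jnc7_usual"), 1, keep_records=True)
        kinds = [rec.kind for rec in r["records"]]
        assert kinds == ["horizon_end"]
        assert r["life_years"] == 10.0
        assert r["counts"].get("deaths_all", 0) == 0

    def test_lifetime_horizon_caps_at_age_100(self, values):
        cohort = make_flat_cohort(age=99.5)
        sim = CohortSim(cohort, toy_values(values), lifetime=True)
        r = sim.run_individual(0, get_strategy("jnc7_usual"), 1)
        assert r["life_years"] == pytest.approx(0.5)

    def test_cohort_of_one_gives_rates_in_thousand_multiples(self, values):
        cohort = make_flat_cohort(n=1)
        sim = CohortSim(cohort, toy_values(values, noncvd=0.2), horizon_years=10.0)
        s = sim.run_cohort(get_strategy("jnc7_usual"), 1)
        assert s.rate_per_1000("deaths_all") % 1000.0 == 0.0


class TestDeterminismAndOrdering:
    def test_replay_is_bit_identical(self, eligible_cohort, values):
        sim = CohortSim(eligible_cohort, values, horizon_years=10.0)
        s = get_strategy("sprint_intensive")
        r1 = sim.run_individual(3, s, 42, iteration=2, keep_records=True)
        r2 = sim.run_individual(3, s, 42, iteration=2, keep_records=True)
        assert records_to_dataframe(r1["records"]).equals(
            records_to_dataframe(r2["records"]))
        assert r1["life_years"] == r2["life_years"]

    def test_cohort_replay_identical(self, tiny_cohort, values):
        sim = CohortSim(tiny_cohort, values, horizon_years=5.0)
        s1 = sim.run_cohort(get_strategy("tbc"), 9)
        s2 = sim.run_cohort(get_strategy("tbc"), 9)
        assert s1.counts == s2.counts
        np.testing.assert_array_equal(s1.mean_sbp_by_year, s2.mean_sbp_by_year)

    def test_times_monotone_and_terminal_is_death_or_horizon(self, eligible_cohort, values):
        sim = CohortSim(eligible_cohort, values, horizon_years=10.0)
        strat = get_strategy("jnc7_usual")
        for i in range(25):
            r = sim.run_individual(i, strat, 7, keep_records=True)
            times = [rec.time for rec in r["records"]]
            assert times == sorted(times)
            last = r["records"][-1]
            if r["alive"]:
                assert last.kind == "horizon_end"
            else:
                assert (last.kind in DEATH_KINDS
                        or (last.kind in FATAL_EVENT_KINDS
                            and last.detail == "fatal"))
                # nothing recorded after the terminal event
                assert all(rec.time <= last.time for rec in r["records"])

    def test_at_most_one_death_and_count_partition(self, eligible_cohort, values):
        sim = CohortSim(eligible_cohort, values, horizon_years=10.0)
        s = sim.run_cohort(get_strategy("accaha_usual"), 21)
        c = s.counts
        assert c.get("deaths_all", 0) <= s.n
        assert c.get("cvd_events", 0) == pytest.approx(
            c.get("chd", 0) + c.get("stroke", 0) + c.get("hf", 0))
        assert c.get("cvd_events", 0) == pytest.approx(
            c.get("first_cvd", 0) + c.get("recurrent_cvd", 0))
        assert c.get("deaths_all", 0) == pytest.approx(
            c.get("cvd_deaths", 0) + c.get("noncvd_deaths", 0)
            + c.get("sae_deaths", 0))
        assert c.get("cvd_deaths", 0) == pytest.approx(
            c.get("acute_cvd_deaths", 0) + c.get("chronic_cvd_deaths", 0))


class TestEngineEquivalence:
    def test_first_event_matches_day_grid_bernoulli_oracle(self, values):
        """DES first-event time and type vs a 1-day-step Bernoulli
        microsimulation of the same constant competing hazards."""
        rates = {"chd": 0.02, "stroke": 0.01, "hf": 0.015,
                 "non_cvd_death": 0.03, "sae": 0.01}
        v = toy_values(values, chd=rates["chd"], stroke=rates["stroke"],
                       hf=rates["hf"], noncvd=rates["non_cvd_death"],
                       sae=rates["sae"], cf=0.0)
        cohort = make_flat_cohort(n_meds=1)
        sim = CohortSim(cohort, v, horizon_years=4.0)
        strat = get_strategy("jnc7_usual")
        n = 4000
        des_times, des_types = [], []
        for it in range(n):
            r = sim.run_individual(0, strat, 5, iteration=it, keep_records=True)
            ev = [rec for rec in r["records"]
                  if rec.kind in ("chd", "stroke", "hf", "non_cvd_death", "sae")]
            if ev:
                des_times.append(ev[0].time)
                des_types.append(ev[0].kind)

        rng = np.random.default_rng(99)
        days = int(4.0 * 365)
        kinds = list(rates)
        first_day = np.full((n, len(kinds)), np.inf)
        for j, k in enumerate(kinds):
            p = rates[k] / 365.0
            draw = rng.geometric(p, size=n).astype(float)   # day of 1st success
            first_day[:, j] = draw
        winner = first_day.argmin(axis=1)
        t_oracle_all = first_day.min(axis=1) / 365.0
        inside = t_oracle_all <= 4.0
        oracle_times = t_oracle_all[inside]
        oracle_types = [kinds[w] for w, i in zip(winner, inside) if i]

        # type distribution: two-sample chi-square on the contingency table
        table = np.array([[des_types.count(k) for k in kinds],
                          [oracle_types.count(k) for k in kinds]])
        _, p_type, _, _ = stats.chi2_contingency(table)
        assert p_type > 0.01
        # time distribution: two-sample KS
        _, p_time = stats.ks_2samp(des_times, oracle_times)
        assert p_time > 0.01
        # event fractions agree
        assert abs(len(des_times) / n - len(oracle_times) / n) < 0.02


class TestCommonRandomNumbers:
    def test_paired_iterations_have_lower_contrast_variance(self, eligible_cohort):
        """Strategy deltas with shared parameter draws and substreams have
        smaller Monte-Carlo variance than a mismatched pairing."""
        from htnsim.config import default_registry, np_substream
        reg = default_registry()
        a, b = [], []
        for it in range(6):
            vals = reg.draw_values(np_substream(3, "psa", it))
            sim = CohortSim(eligible_cohort, vals, horizon_years=5.0)
            a.append(sim.run_cohort(get_strategy("jnc7_usual"), 3, it)
                     .rate_per_1000("cvd_events"))
            b.append(sim.run_cohort(get_strategy("sprint_intensive"), 3, it)
                     .rate_per_1000("cvd_events"))
        paired = np.var([x - y for x, y in zip(a, b)])
        mismatched = np.var([x - y for x, y in zip(a, b[1:] + b[:1])])
        assert paired < mismatched

    def test_identical_strategies_give_identical_summaries(self, tiny_cohort, values):
        """Same goals and care parameters -> identical output under CRN."""
        import htnsim.care_process as cp
        clone = cp.Strategy("jnc7_clone", "jnc7", (140.0, 90.0), "usual", 0.0)
        sim = CohortSim(tiny_cohort, values, horizon_years=5.0)
        s1 = sim.run_cohort(cp.get_strategy("jnc7_usual"), 13)
        s2 = sim.run_cohort(clone, 13)
        assert s1.counts == s2.counts
        np.testing.assert_array_equal(s1.mean_sbp_by_year, s2.mean_sbp_by_year)
        assert s1.life_years == s2.life_years
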