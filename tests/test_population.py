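import numpy as np
import pandas as pd
import pytest
from scipy import stats

from htnsim.config import ConfigurationError
from htnsim.population import (Cohort, EligibilityRule, TRAJ_AGES,
                               apply_sprint_eligibility,
                               default_eligibility_rules,
                               default_population_spec, default_raking_margins,
                               generate_base_population, rake_weights,
                               sample_with_replacement,
                               standardized_mean_difference, trajectory_value,
                               weight_cohort, weighted_mean_sd)
from htnsim.risk_engine import ten_year_cvd_risk


def _with_risk(cohort, values):
    cohort.individuals["risk10"] = ten_year_cvd_risk(cohort.individuals, values)
    return cohort


class TestGeneration:
    def test_zero_request_is_an_error(self):
        with pytest.raises(ConfigurationError):
            generate_base_population(0, seed=1)

    def test_same_seed_is_bit_identical(self):
        a = generate_base_population(300, seed=5)
        b = generate_base_population(300, seed=5)
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        for f in a.trajectories:
            np.testing.assert_array_equal(a.trajectories[f], b.trajectories[f])

    def test_different_seed_differs(self):
        a = generate_base_population(100, seed=5)
        b = generate_base_population(100, seed=6)
        assert not a.individuals["sbp"].equals(b.individuals["sbp"])

    def test_invalid_correlation_matrix_rejected(self):
        spec = default_population_spec()
        spec.correlations += [("sbp", "bmi", 0.95), ("bmi", "hdl", 0.95),
                              ("sbp", "hdl", -0.95)]
        with pytest.raises(ConfigurationError, match="positive semidefinite"):
            generate_base_population(50, seed=1, spec=spec)

    def test_invariants_hold(self):
        df = generate_base_population(500, seed=2).individuals
        assert (df["sbp"] > df["dbp"]).all()
        assert (df["dbp"] > 0).all()
        assert (df["egfr"] > 0).all()
        assert ((df["ckd"] == 1) == (df["egfr"] < 60)).all()

    def test_weighted_baseline_sbp_matches_design_target(self, registry, values):
        """Eligible + raked cohort centres near the 138.6 mm Hg baseline."""
        base = _with_risk(generate_base_population(8000, seed=3), values)
        eligible = apply_sprint_eligibility(base)
        weighted = weight_cohort(eligible, "sprint_representative")
        m, _ = weighted_mean_sd(weighted.individuals["sbp"].to_numpy(),
                                weighted.individuals["weight"].to_numpy())
        assert abs(m - 138.6) < 1.5


class TestTrajectories:
    def test_anchored_at_baseline_and_continuous(self):
        cohort = generate_base_population(50, seed=4)
        df = cohort.individuals
        for i in (0, 17):
            row = int(df.loc[i, "traj_row"])
            age0 = float(df.loc[i, "baseline_age"])
            assert trajectory_value(cohort, "sbp", row, age0) == pytest.approx(
                float(df.loc[i, "sbp"]), abs=1e-9)
            ages = np.linspace(30, 99, 400)
            vals = [trajectory_value(cohort, "sbp", row, a) for a in ages]
            assert np.max(np.abs(np.diff(vals))) < 1.0  # no jumps on a fine grid

    def test_evaluation_clamped_to_age_support(self):
        cohort = generate_base_population(5, seed=4)
        lo = trajectory_value(cohort, "egfr", 0, 10.0)
        assert lo == trajectory_value(cohort, "egfr", 0, TRAJ_AGES[0])
        hi = trajectory_value(cohort, "egfr", 0, 120.0)
        assert hi == trajectory_value(cohort, "egfr", 0, TRAJ_AGES[-1])


class TestEligibility:
    def test_default_rules_match_brute_force(self, values):
        """Rule-set output equals independent row-by-row rule evaluation."""
        cohort = _with_risk(generate_base_population(1500, seed=6), values)
        got = set(apply_sprint_eligibility(cohort).individuals["id"])
        caps = {0: 180, 1: 180, 2: 170, 3: 160, 4: 150}
        expected = set()
        for _, r in cohort.individuals.iterrows():
            if r.baseline_age < 50 or r.diabetes == 1 or r.egfr < 20:
                continue
            if int(r.n_meds) not in caps:
                continue
            if not (130 <= r.sbp <= caps[int(r.n_meds)]):
                continue
            if not (r.clinical_cvd == 1 or 20 <= r.egfr < 60
                    or r.baseline_age >= 75 or r.risk10 >= 0.15):
                continue
            expected.add(r.id)
        assert got == expected
        # spot checks from the rule definitions
        young = cohort.individuals[cohort.individuals.baseline_age < 50]
        assert not (set(young["id"]) & got)
        diabetic = cohort.individuals[cohort.individuals.diabetes == 1]
        assert not (set(diabetic["id"]) & got)

    def test_empty_rule_set_is_identity(self):
        cohort = generate_base_population(100, seed=6)
        out = apply_sprint_eligibility(cohort, rules=[])
        assert len(out) == len(cohort)

    def test_adding_a_rule_never_increases_count(self, values):
        cohort = _with_risk(generate_base_population(800, seed=8), values)
        rules = default_eligibility_rules()
        n_prev = len(apply_sprint_eligibility(cohort, rules=[]))
        for k in range(1, len(rules) + 1):
            n = len(apply_sprint_eligibility(cohort, rules=rules[:k]))
            assert n <= n_prev
            n_prev = n

    def test_missing_field_is_data_error(self):
        cohort = generate_base_population(20, seed=6)
        rule = EligibilityRule("bad", "min", field="nonexistent", value=1)
        with pytest.raises(Exception, match="missing field"):
            apply_sprint_eligibility(cohort, rules=[rule])


class TestWeighting:
    def test_national_weights_sum_to_population_total(self, values):
        cohort = _with_risk(generate_base_population(2000, seed=9), values)
        eligible = apply_sprint_eligibility(cohort)
        out = weight_cohort(eligible, "national", population_total=18_100_000.0)
        total = out.individuals["weight"].sum()
        assert total == pytest.approx(18_100_000.0, rel=1e-6)

    def test_raking_with_targets_equal_to_cohort_margins_is_uniform(self):
        df = generate_base_population(500, seed=10).individuals
        p = df["female"].mean()
        w = rake_weights(df, [{"field": "female", "cuts": None,
                               "targets": {0: 1 - p, 1: p}}])
        assert np.allclose(w, 1.0, atol=1e-6)

    def test_raked_smd_below_threshold(self, values):
        """Post-raking standardized mean differences on targeted margins <= 0.10."""
        cohort = _with_risk(generate_base_population(6000, seed=11), values)
        eligible = apply_sprint_eligibility(cohort)
        out = weight_cohort(eligible, "sprint_representative")
        df = out.individuals
        w = df["weight"].to_numpy()
        for margin in default_raking_margins():
            if margin["cuts"] is not None:
                continue
            target_p = margin["targets"][1]
            cohort_p = float(np.average(df[margin["field"]].to_numpy(), weights=w))
            assert abs(standardized_mean_difference(target_p, cohort_p)) <= 0.10

    def test_unknown_mode_rejected(self, eligible_cohort):
        with pytest.raises(ConfigurationError):
            weight_cohort(eligible_cohort, "bogus")


class TestResampling:
    def test_sample_size_and_reproducibility(self, eligible_cohort):
        a = sample_with_replacement(eligible_cohort, 250, seed=3)
        b = sample_with_replacement(eligible_cohort, 250, seed=3)
        assert len(a) == 250
        pd.testing.assert_frame_equal(a.individuals, b.individuals)

    def test_single_individual_cohort_gives_copies(self, eligible_cohort):
        one = Cohort(eligible_cohort.individuals.iloc[:1].copy(),
                     eligible_cohort.trajectories)
        out = sample_with_replacement(one, 12, seed=1)
        assert (out.individuals["traj_row"]
                == one.individuals["traj_row"].iloc[0]).all()

    def test_draw_frequencies_match_weights(self, eligible_cohort):
        """Chi-square goodness of fit of draw counts vs a 3-person weight vector."""
        three = Cohort(eligible_cohort.individuals.iloc[:3].copy().reset_index(drop=True),
                       eligible_cohort.trajectories)
        three.individuals["weight"] = [0.2, 0.3, 0.5]
        out = sample_with_replacement(three, 30_000, seed=5)
        counts = out.individuals["traj_row"].value_counts()
        rows = three.individuals["traj_row"].tolist()
        observed = [counts.get(r, 0) for r in rows]
        _, pval = stats.chisquare(observed, f_exp=[0.2 * 30_000, 0.3 * 30_000, 0.5 * 30_000])
        assert pval > 0.01

    def test_all_zero_weights_rejected(self, eligible_cohort):
        bad = eligible_cohort.copy()
        bad.individuals["weight"] = 0.0
        with pytest.raises(Exception, match="zero"):
            sample_with_replacement(bad, 10, seed=1)


class TestSMD:
    @pytest.mark.parametrize("target,cohort,expected", [
        ((3.0, 1.0), (3.0, 2.0), 0.0),
        ((1.0, 1.0), (0.0, 1.0), 1.0),
        # pooled-proportion formula evaluated by hand:
        # (0.5-0.3)/sqrt((0.25+0.21)/2) = 0.2/sqrt(0.23)
        (0.5, 0.3, 0.2 / np.sqrt(0.23)),
    ])
    def test_known_values(self, target, cohort, expected):
        assert standardized_mean_difference(target, cohort) == pytest.approx(expected)

    def test_zero_pooled_sd_is_error(self):
        with pytest.raises(Exception):
            standardized_mean_difference((1.0, 0.0), (2.0, 0.0))
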