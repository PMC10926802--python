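"""Synthetic cohort with age-indexed risk-factor trajectories.

Emulates a survey-derived sample of US adults carrying lifetime (age 18-99)
risk-factor trajectories, filtered to intensive-BP-trial eligibility and
weighted two ways: *sprint_representative* (raked so baseline characteristics
match the trial's published baseline table) and *national* (scaled to the
configured national total of trial-eligible adults).

Risk factors are drawn from a Gaussian copula with configurable marginals
(normal / lognormal / Bernoulli / categorical) and a pairwise correlation
structure; each continuous factor then receives a deterministic piecewise-
linear age trajectory anchored at its baseline value.  Diabetes is a
trajectory too: an indicator that switches on at a pre-drawn onset age.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, np_substream

__all__ = [
    "Cohort",
    "PopulationSpec",
    "EligibilityRule",
    "default_population_spec",
    "default_eligibility_rules",
    "default_raking_margins",
    "generate_base_population",
    "apply_sprint_eligibility",
    "weight_cohort",
    "sample_with_replacement",
    "standardized_mean_difference",
    "trajectory_value",
    "TRAJ_AGES",
]

#: Integer age grid on which all trajectories are tabulated.
TRAJ_AGES = np.arange(18, 100)

#: Continuous factors that carry trajectories.
TRAJECTORY_FACTORS = ("sbp", "dbp", "bmi", "hdl", "ldl", "egfr")


class DataError(ValueError):
    """Raised when cohort data violate an operation's requirements."""


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Marginal distributions, correlations, and trajectory slopes.

    ``marginals`` maps factor name to a distribution spec:
      ``{"dist": "normal", "mean": m, "sd": s, "clip": [lo, hi]}``
      ``{"dist": "lognormal", "mu": m, "sigma": s}``
      ``{"dist": "bernoulli", "p": p}``
      ``{"dist": "categorical", "probs": [...], "values": [...]}``
    ``correlations`` is a list of ``(factor_a, factor_b, rho)`` on the latent
    Gaussian scale.  ``trajectory_slopes`` maps factor -> list of
    ``(age_knot, slope_per_year)`` pairs; the slope applies from that knot to
    the next.
    """

    marginals: dict = field(default_factory=dict)
    correlations: list = field(default_factory=list)
    trajectory_slopes: dict = field(default_factory=dict)
    diabetes_onset_mean_years: float = 60.0

    def factor_order(self) -> list[str]:
        return list(self.marginals)


def default_population_spec() -> PopulationSpec:
    """Defaults chosen so the eligible, raked cohort resembles the trial
    baseline table (mean age ~68, 36% female, mean SBP ~139, ~2 meds)."""
    marginals = {
        "baseline_age": {"dist": "normal", "mean": 67.0, "sd": 9.5, "clip": [45.0, 95.0]},
        "female": {"dist": "bernoulli", "p": 0.36},
        "race_black": {"dist": "bernoulli", "p": 0.30},
        "smoker": {"dist": "bernoulli", "p": 0.14},
        "sbp": {"dist": "normal", "mean": 138.0, "sd": 12.0, "clip": [90.0, 220.0]},
        "dbp": {"dist": "normal", "mean": 78.0, "sd": 11.0, "clip": [40.0, 130.0]},
        "bmi": {"dist": "normal", "mean": 29.9, "sd": 5.8, "clip": [16.0, 60.0]},
        "hdl": {"dist": "normal", "mean": 52.9, "sd": 14.4, "clip": [15.0, 120.0]},
        "ldl": {"dist": "normal", "mean": 112.0, "sd": 30.0, "clip": [30.0, 300.0]},
        "egfr": {"dist": "normal", "mean": 72.0, "sd": 20.0, "clip": [12.0, 150.0]},
        "diabetes": {"dist": "bernoulli", "p": 0.10},
        "clinical_cvd": {"dist": "bernoulli", "p": 0.18},
        "n_meds": {"dist": "categorical",
                   "probs": [0.09, 0.30, 0.33, 0.20, 0.08],
                   "values": [0, 1, 2, 3, 4]},
    }
    correlations = [
        ("baseline_age", "sbp", 0.20),
        ("baseline_age", "egfr", -0.45),
        ("baseline_age", "clinical_cvd", 0.25),
        ("baseline_age", "n_meds", 0.20),
        ("baseline_age", "dbp", -0.15),
        ("sbp", "dbp", 0.50),
        ("bmi", "dbp", 0.15),
        ("bmi", "hdl", -0.30),
        ("bmi", "diabetes", 0.25),
        ("n_meds", "clinical_cvd", 0.20),
    ]
    trajectory_slopes = {
        "sbp": [(18, 0.8), (60, 0.5), (70, 0.2), (80, 0.0)],
        "dbp": [(18, 0.4), (55, -0.20), (90, -0.30)],
        "bmi": [(18, 0.15), (60, 0.0), (75, -0.10)],
        "hdl": [(18, 0.0)],
        "ldl": [(18, 0.5), (50, 0.0), (70, -0.5)],
        "egfr": [(18, -0.4), (60, -0.9), (75, -1.3)],
    }
    return PopulationSpec(marginals, correlations, trajectory_slopes)


@dataclass
class Cohort:
    """Individuals table + per-factor trajectory matrices on TRAJ_AGES.

    ``individuals`` rows align positionally with trajectory matrix rows; the
    ``id`` column survives resampling so repeated draws of one source
    individual share a trajectory row via ``traj_row``.
    """

    individuals: pd.DataFrame
    trajectories: dict[str, np.ndarray]

    def __len__(self) -> int:
        return len(self.individuals)

    def copy(self) -> "Cohort":
        return Cohort(self.individuals.copy(), dict(self.trajectories))

    # -- I/O -------------------------------------------------------------
    def to_csv(self, individuals_path, trajectories_path=None) -> None:
        self.individuals.to_csv(individuals_path, index=False)
        if trajectories_path is not None:
            self.trajectories_long().to_csv(trajectories_path, index=False)

    def trajectories_long(self) -> pd.DataFrame:
        """Long format (id, factor, age, value), one row per grid point."""
        ids = self.individuals["id"].to_numpy()
        rows = self.individuals["traj_row"].to_numpy()
        frames = []
        for factor, mat in self.trajectories.items():
            sub = mat[rows]
            frames.append(pd.DataFrame({
                "id": np.repeat(ids, len(TRAJ_AGES)),
                "factor": factor,
                "age": np.tile(TRAJ_AGES, len(ids)),
                "value": sub.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _build_correlation_matrix(order: Sequence[str], pairs) -> np.ndarray:
    k = len(order)
    idx = {f: i for i, f in enumerate(order)}
    R = np.eye(k)
    for a, b, rho in pairs:
        if a not in idx or b not in idx:
            raise ConfigurationError(f"correlation references unknown factor ({a}, {b})")
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ConfigurationError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {eig.min():.3g})"
        )
    return R


def _marginal_transform(u: np.ndarray, spec: Mapping) -> np.ndarray:
    dist = spec.get("dist")
    if dist == "normal":
        x = stats.norm.ppf(u, loc=spec["mean"], scale=spec["sd"])
    elif dist == "lognormal":
        x = np.exp(stats.norm.ppf(u, loc=spec["mu"], scale=spec["sigma"]))
    elif dist == "bernoulli":
        return (u > 1.0 - spec["p"]).astype(np.int64)
    elif dist == "categorical":
        cum = np.cumsum(spec["probs"])
        if abs(cum[-1] - 1.0) > 1e-9:
            raise ConfigurationError("categorical probs must sum to 1")
        x = np.asarray(spec["values"])[np.searchsorted(cum, u, side="right").clip(0, len(cum) - 1)]
        return x
    else:
        raise ConfigurationError(f"unknown marginal distribution {dist!r}")
    if "clip" in spec:
        x = np.clip(x, spec["clip"][0], spec["clip"][1])
    return x


def _slopes_on_grid(knots: Sequence, ages: np.ndarray) -> np.ndarray:
    """Per-year slope at each grid age from (knot, slope) pairs."""
    knots = sorted(knots)
    s = np.zeros_like(ages, dtype=float)
    for age_knot, slope in knots:
        s[ages >= age_knot] = slope
    return s


def _anchor_trajectory(baseline_age: np.ndarray, baseline_value: np.ndarray,
                       slope_grid: np.ndarray) -> np.ndarray:
    """Integrate slopes over the grid, anchored so value(baseline_age)=baseline."""
    # cumulative drift from age 18 to each grid age (trapezoid-free: slopes
    # are piecewise constant per one-year step)
    cum = np.concatenate([[0.0], np.cumsum(slope_grid[:-1])])
    # drift at each individual's (continuous) baseline age
    base_drift = np.interp(baseline_age, TRAJ_AGES, cum)
    return baseline_value[:, None] + (cum[None, :] - base_drift[:, None])


def generate_base_population(n: int, seed: int,
                             spec: PopulationSpec | None = None) -> Cohort:
    """Draw ``n`` individuals with complete fields and one trajectory per factor.

    Reproducible: the same ``(n, seed, spec)`` yields a bit-identical cohort.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    spec = spec or default_population_spec()
    order = spec.factor_order()
    R = _build_correlation_matrix(order, spec.correlations)
    rng = np_substream(seed, "population", "copula")
    # nearest-PD safeguard for exactly-singular matrices
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(order)))
    Z = rng.standard_normal((n, len(order))) @ L.T
    U = stats.norm.cdf(Z)

    cols: dict[str, np.ndarray] = {}
    for j, factor in enumerate(order):
        cols[factor] = _marginal_transform(U[:, j], spec.marginals[factor])

    df = pd.DataFrame(cols)
    df.insert(0, "id", np.arange(n))
    df["sex"] = np.where(df["female"] == 1, "female", "male")
    # physiological coherence: SBP strictly above DBP
    df["dbp"] = np.minimum(df["dbp"], df["sbp"] - 15.0)
    df["ckd"] = (df["egfr"] < 60.0).astype(np.int64)
    # diabetes onset age: baseline diabetics at baseline, others exponential waiting time
    onset_rng = np_substream(seed, "population", "diabetes_onset")
    wait = onset_rng.exponential(spec.diabetes_onset_mean_years, n)
    df["diabetes_onset_age"] = np.where(df["diabetes"] == 1, df["baseline_age"],
                                        df["baseline_age"] + wait)
    df["weight_sprint"] = 1.0
    df["weight_national"] = 1.0
    df["traj_row"] = np.arange(n)

    trajectories = {}
    for factor in TRAJECTORY_FACTORS:
        slope_grid = _slopes_on_grid(spec.trajectory_slopes.get(factor, [(18, 0.0)]),
                                     TRAJ_AGES)
        trajectories[factor] = _anchor_trajectory(
            df["baseline_age"].to_numpy(), df[factor].to_numpy(), slope_grid)
    return Cohort(df, trajectories)


def trajectory_value(cohort: Cohort, factor: str, row: int, age: float) -> float:
    """Piecewise-linear interpolation of one factor at a continuous age.

    Ages are clamped to the [18, 99] support.
    """
    age = min(max(age, TRAJ_AGES[0]), TRAJ_AGES[-1])
    return float(np.interp(age, TRAJ_AGES, cohort.trajectories[factor][row]))


# --------------------------------------------------------------------------
# Eligibility
# --------------------------------------------------------------------------

@dataclass
class EligibilityRule:
    """One data-driven inclusion/exclusion rule.

    kinds:
      ``min`` / ``max``: field >= / <= value
      ``exclude_flag``: field must be 0
      ``sbp_med_window``: SBP within [low, cap(n_meds)]; med counts beyond the
        cap list are excluded
      ``elevated_risk``: at least one of clinical CVD, eGFR in [20, 60),
        10-year CVD risk >= threshold (requires ``risk10`` column), age >= 75
    """

    name: str
    kind: str
    field: str | None = None
    value: float | None = None
    sbp_low: float = 130.0
    sbp_caps: Sequence[float] = (180.0, 180.0, 170.0, 160.0, 150.0)
    risk_threshold: float = 0.15

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        def col(name):
            if name not in df.columns:
                raise DataError(f"eligibility rule {self.name!r} references missing field {name!r}")
            return df[name].to_numpy()

        if self.kind == "min":
            return col(self.field) >= self.value
        if self.kind == "max":
            return col(self.field) <= self.value
        if self.kind == "exclude_flag":
            return col(self.field) == 0
        if self.kind == "sbp_med_window":
            sbp, meds = col("sbp"), col("n_meds").astype(int)
            caps = np.asarray(self.sbp_caps, dtype=float)
            ok_meds = meds < len(caps)
            cap = np.where(ok_meds, caps[np.clip(meds, 0, len(caps) - 1)], -np.inf)
            return ok_meds & (sbp >= self.sbp_low) & (sbp <= cap)
        if self.kind == "elevated_risk":
            egfr = col("egfr")
            any_risk = (col("clinical_cvd") == 1)
            any_risk |= (egfr >= 20.0) & (egfr < 60.0)
            any_risk |= col("baseline_age") >= 75.0
            any_risk |= col("risk10") >= self.risk_threshold
            return any_risk
        raise ConfigurationError(f"unknown eligibility rule kind {self.kind!r}")


def default_eligibility_rules() -> list[EligibilityRule]:
    """Published intensive-BP-trial criteria: age >= 50, SBP 130-180 with
    medication-count-dependent caps, elevated CVD risk, no diabetes, no very
    advanced kidney disease."""
    return [
        EligibilityRule("age_floor", "min", field="baseline_age", value=50.0),
        EligibilityRule("sbp_window", "sbp_med_window"),
        EligibilityRule("no_diabetes", "exclude_flag", field="diabetes"),
        EligibilityRule("egfr_floor", "min", field="egfr", value=20.0),
        EligibilityRule("elevated_risk", "elevated_risk"),
    ]


def apply_sprint_eligibility(cohort: Cohort,
                             rules: Sequence[EligibilityRule] | None = None) -> Cohort:
    """Keep only individuals passing every rule (empty rule set = identity)."""
    if rules is None:
        rules = default_eligibility_rules()
    df = cohort.individuals
    mask = np.ones(len(df), dtype=bool)
    for rule in rules:
        mask &= rule.mask(df)
    return Cohort(df.loc[mask].reset_index(drop=True), cohort.trajectories)


# --------------------------------------------------------------------------
# Weighting
# --------------------------------------------------------------------------

def default_raking_margins() -> list[dict]:
    """Raking margins matching the trial's published baseline characteristics.

    Each margin: ``{"name", "bins": callable(df)->int codes, "targets": {code: prop}}``
    expressed declaratively with field/cutpoints so it round-trips through config.
    """
    return [
        {"field": "female", "cuts": None, "targets": {0: 0.644, 1: 0.356}},
        {"field": "baseline_age", "cuts": [60.0, 70.0, 75.0],
         "targets": {0: 0.17, 1: 0.37, 2: 0.18, 3: 0.28}},
        {"field": "sbp", "cuts": [132.0, 145.0],
         "targets": {0: 0.40, 1: 0.34, 2: 0.26}},
        {"field": "clinical_cvd", "cuts": None, "targets": {0: 0.80, 1: 0.20}},
        {"field": "smoker", "cuts": None, "targets": {0: 0.867, 1: 0.133}},
        {"field": "ckd", "cuts": None, "targets": {0: 0.717, 1: 0.283}},
        {"field": "race_black", "cuts": None, "targets": {0: 0.70, 1: 0.30}},
    ]


class CalibrationError(RuntimeError):
    """Raking failed to converge."""


def _margin_codes(df: pd.DataFrame, margin: Mapping) -> np.ndarray:
    x = df[margin["field"]].to_numpy()
    cuts = margin.get("cuts")
    if cuts is None:
        return x.astype(int)
    return np.searchsorted(np.asarray(cuts, dtype=float), x, side="right")


def rake_weights(df: pd.DataFrame, margins: Sequence[Mapping],
                 tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Iterative proportional fitting to the margin targets; returns weights
    summing to len(df)."""
    n = len(df)
    w = np.ones(n)
    codes = [(_margin_codes(df, m), m["targets"]) for m in margins]
    for _ in range(max_iter):
        max_adj = 0.0
        for code, targets in codes:
            for cell, target in targets.items():
                sel = code == cell
                cur = w[sel].sum() / w.sum()
                if cur <= 0:
                    if target > 0:
                        raise CalibrationError(
                            f"raking cell {cell} empty but target {target} > 0")
                    continue
                f = target / cur
                w[sel] *= f
                max_adj = max(max_adj, abs(f - 1.0))
        if max_adj < tol:
            break
    else:
        raise CalibrationError(
            f"raking did not converge in {max_iter} iterations (last adj {max_adj:.2e})")
    return w * (n / w.sum())


def weight_cohort(cohort: Cohort, mode: str,
                  margins: Sequence[Mapping] | None = None,
                  population_total: float = 18_100_000.0) -> Cohort:
    """Activate one weighting scheme.

    ``sprint_representative``: rake to the margin targets; weights sum to n.
    ``national``: base (survey-style) weights scaled to ``population_total``.
    """
    out = cohort.copy()
    df = out.individuals
    if mode == "sprint_representative":
        margins = default_raking_margins() if margins is None else margins
        df["weight_sprint"] = rake_weights(df, margins)
        df["weight"] = df["weight_sprint"]
    elif mode == "national":
        base = df["weight_national"].to_numpy()
        df["weight_national"] = base * (population_total / base.sum())
        df["weight"] = df["weight_national"]
    else:
        raise ConfigurationError(f"unknown weighting mode {mode!r}")
    return out


def sample_with_replacement(cohort: Cohort, n: int, seed: int) -> Cohort:
    """Draw an analysis cohort of ``n`` individuals, probability proportional
    to the active weight."""
    if n <= 0:
        raise ConfigurationError("n must be positive")
    df = cohort.individuals
    if "weight" not in df.columns:
        raise DataError("no active weights: call weight_cohort first")
    w = df["weight"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise DataError("all weights are zero")
    rng = np_substream(seed, "population", "resample")
    idx = rng.choice(len(df), size=n, replace=True, p=w / w.sum())
    sampled = df.iloc[idx].reset_index(drop=True)
    sampled["id"] = np.arange(n)
    return Cohort(sampled, cohort.trajectories)


# --------------------------------------------------------------------------
# Diagnostics
# --------------------------------------------------------------------------

def standardized_mean_difference(target, cohort) -> float:
    """Signed SMD between a target moment and a (weighted) cohort moment.

    Continuous: pass ``(mean, sd)`` tuples for both.  Proportions: pass bare
    floats in (0, 1); the pooled-proportion formula is used.
    """
    if isinstance(target, tuple) and isinstance(cohort, tuple):
        (m1, s1), (m2, s2) = target, cohort
        pooled = np.sqrt((s1**2 + s2**2) / 2.0)
        if pooled <= 0:
            raise DataError("zero pooled SD: SMD undefined")
        return float((m1 - m2) / pooled)
    p1, p2 = float(target), float(cohort)
    pooled = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if pooled <= 0:
        raise DataError("zero pooled SD: SMD undefined")
    return float((p1 - p2) / pooled)


def weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    v = float(np.average((x - m) ** 2, weights=w))
    return m, float(np.sqrt(v))
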