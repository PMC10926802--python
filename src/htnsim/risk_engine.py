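"""Hazard models and event-time sampling.

Incident coronary heart disease (CHD), stroke, heart failure (HF), and non-CVD
death follow Cox-type proportional hazards: a piecewise-constant baseline rate
by age band and sex (evaluated at a reference covariate profile) multiplied by
``exp(beta' x)`` over the individual's risk factors and by treatment-effect
hazard ratios for medication-induced SBP lowering.  Recurrent CVD events,
chronic CVD death among survivors, treatment-related serious adverse events
(SAEs), and intolerable adverse events (IAEs) follow lookup-table rates.

Convention for time-varying covariates: hazards are held piecewise constant
between state-update boundaries (visits, annual birthdays, events); event
times are sampled by inversion on the resulting piecewise-exponential
survival curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AGE_BANDS, ConfigurationError, age_band_index

__all__ = [
    "CoxRiskModel",
    "build_models",
    "hazard",
    "linear_predictor_df",
    "sbp_effect_hr",
    "sample_event_time",
    "sae_event_rate",
    "iae_event_rate",
    "resolve_sae",
    "recurrent_event_rate",
    "chronic_cvd_death_rate",
    "acute_case_fatality",
    "ten_year_cvd_risk",
]

CVD_OUTCOMES = ("chd", "stroke", "hf")

#: Reference profile at which the baseline tables are tabulated.
REF = {"sbp": 120.0, "bmi": 25.0, "hdl": 50.0, "ldl": 110.0}

#: Plausible physiological bounds used to clamp covariates before the
#: exponential (wildly out-of-range values are clamped, not propagated).
_BOUNDS = {"sbp": (70.0, 250.0), "bmi": (12.0, 80.0),
           "hdl": (10.0, 150.0), "ldl": (20.0, 400.0)}


class DataError(ValueError):
    pass


@dataclass
class CoxRiskModel:
    """One outcome's proportional-hazards specification."""

    outcome: str
    coefficients: dict[str, float]
    baseline_female: Sequence[float]
    baseline_male: Sequence[float]

    def baseline(self, age: float, female: bool) -> float:
        tab = self.baseline_female if female else self.baseline_male
        return float(tab[age_band_index(age)])


def build_models(values: Mapping) -> dict[str, CoxRiskModel]:
    """Assemble the four Cox models from a registry value mapping."""
    out = {}
    for outcome in (*CVD_OUTCOMES, "noncvd_death"):
        key = "noncvd_death" if outcome == "noncvd_death" else outcome
        out[outcome] = CoxRiskModel(
            outcome=outcome,
            coefficients=dict(values[f"coef_{'noncvd_death' if outcome == 'noncvd_death' else outcome}"]),
            baseline_female=values[f"h0_{'noncvd_death' if outcome == 'noncvd_death' else outcome}_female"],
            baseline_male=values[f"h0_{'noncvd_death' if outcome == 'noncvd_death' else outcome}_male"],
        )
    return out


def _clamp(name: str, x: float) -> float:
    lo, hi = _BOUNDS[name]
    return min(max(x, lo), hi)


def linear_predictor(coefs: Mapping[str, float], state: Mapping) -> float:
    """beta' x at the individual's current covariates (reference-centred)."""
    lp = 0.0
    lp += coefs.get("smoker", 0.0) * state.get("smoker", 0)
    lp += coefs.get("sbp_per10", 0.0) * (_clamp("sbp", state["sbp"]) - REF["sbp"]) / 10.0
    lp += coefs.get("bmi_per5", 0.0) * (_clamp("bmi", state["bmi"]) - REF["bmi"]) / 5.0
    lp += coefs.get("diabetes", 0.0) * state.get("diabetes", 0)
    lp += coefs.get("hdl_per10", 0.0) * (_clamp("hdl", state["hdl"]) - REF["hdl"]) / 10.0
    lp += coefs.get("ldl_per10", 0.0) * (_clamp("ldl", state["ldl"]) - REF["ldl"]) / 10.0
    lp += coefs.get("ckd", 0.0) * state.get("ckd", 0)
    lp += coefs.get("race_black", 0.0) * state.get("race_black", 0)
    return lp


def linear_predictor_df(coefs: Mapping[str, float], df: pd.DataFrame,
                        sbp_col: str = "sbp") -> np.ndarray:
    """Vectorised linear predictor over a cohort table."""
    lp = np.zeros(len(df))
    lp += coefs.get("smoker", 0.0) * df["smoker"].to_numpy()
    lp += coefs.get("sbp_per10", 0.0) * (df[sbp_col].to_numpy().clip(*_BOUNDS["sbp"]) - REF["sbp"]) / 10.0
    lp += coefs.get("bmi_per5", 0.0) * (df["bmi"].to_numpy().clip(*_BOUNDS["bmi"]) - REF["bmi"]) / 5.0
    lp += coefs.get("diabetes", 0.0) * df["diabetes"].to_numpy()
    lp += coefs.get("hdl_per10", 0.0) * (df["hdl"].to_numpy().clip(*_BOUNDS["hdl"]) - REF["hdl"]) / 10.0
    lp += coefs.get("ldl_per10", 0.0) * (df["ldl"].to_numpy().clip(*_BOUNDS["ldl"]) - REF["ldl"]) / 10.0
    lp += coefs.get("ckd", 0.0) * df["ckd"].to_numpy()
    lp += coefs.get("race_black", 0.0) * df["race_black"].to_numpy()
    return lp


def hazard(model: CoxRiskModel, state: Mapping, treatment_hr: float = 1.0) -> float:
    """lambda(t) = baseline(age, sex) * exp(beta' x) * treatment HR product.

    ``state`` must provide age, female, and the model's covariates; missing
    covariates raise a data error via KeyError on required fields.
    """
    try:
        lam = model.baseline(state["age"], bool(state["female"])) \
            * math.exp(linear_predictor(model.coefficients, state)) * treatment_hr
    except KeyError as exc:
        raise DataError(f"missing covariate {exc} for {model.outcome} hazard") from exc
    if not (lam >= 0.0 and math.isfinite(lam)):
        raise DataError(f"non-finite hazard for {model.outcome}")
    return lam


def sbp_effect_hr(hr_per_10: float, delta_sbp: float) -> float:
    """Treatment-effect HR for ``delta_sbp`` mm Hg of medication-induced lowering.

    ``HR = hr_per_10 ** (delta / 10)``; HR per 10 must lie in (0, 1] so
    lowering SBP can never raise a hazard.
    """
    if not (0.0 < hr_per_10 <= 1.0):
        raise ConfigurationError(f"hr_per_10 must be in (0, 1], got {hr_per_10}")
    if delta_sbp < 0:
        raise ConfigurationError("delta_sbp must be nonnegative (a lowering)")
    return hr_per_10 ** (delta_sbp / 10.0)


def sample_event_time(segments: Sequence[tuple[float, float, float]], rng) -> float:
    """Inversion sampling on a piecewise-constant hazard.

    ``segments`` is a chronological list of ``(t_start, t_end, rate)``.
    Returns the sampled event time, or ``inf`` if the integrated hazard is
    exhausted without an event.
    """
    target = rng.expovariate(1.0)  # Exp(1) threshold on cumulative hazard
    cum = 0.0
    for t0, t1, rate in segments:
        if rate < 0:
            raise ConfigurationError("negative hazard rate")
        seg = rate * (t1 - t0)
        if cum + seg >= target:
            return t0 + (target - cum) / rate
        cum += seg
    return math.inf


# --------------------------------------------------------------------------
# Adverse events & secondary CVD tables
# --------------------------------------------------------------------------

def _meds_lookup(table: Sequence[float], n_meds: int) -> float:
    i = min(max(int(n_meds), 0), len(table) - 1)
    return float(table[i])


def sae_event_rate(values: Mapping, n_meds: int) -> float:
    """Annual treatment-related SAE rate at the current medication count."""
    return _meds_lookup(values["sae_rate_by_meds"], n_meds) * values["sae_rate_scale"]


def iae_event_rate(values: Mapping, n_meds: int) -> float:
    """Annual intolerable-adverse-event rate at the current medication count."""
    return _meds_lookup(values["iae_rate_by_meds"], n_meds) * values["iae_rate_scale"]


def fatal_sae_prob(values: Mapping, age: float) -> float:
    p = values["fatal_sae_prob_by_age"][age_band_index(age)] * values["fatal_sae_scale"]
    return min(max(p, 0.0), 1.0)


def resolve_sae(age: float, values: Mapping, rng) -> str:
    """SAE consequence: ``fatal`` with the age-band probability, else a
    nonfatal hospitalization."""
    return "fatal" if rng.random() < fatal_sae_prob(values, age) else "nonfatal"


def recurrent_event_rate(values: Mapping, age: float, female: bool,
                         cvd_history: bool) -> float:
    """Annual recurrent/secondary CVD event rate (only with CVD history)."""
    if not cvd_history:
        return 0.0
    tab = values["recurrent_cvd_female" if female else "recurrent_cvd_male"]
    return float(tab[age_band_index(age)]) * values["recurrent_cvd_scale"]


def chronic_cvd_death_rate(values: Mapping, age: float, female: bool,
                           cvd_history: bool) -> float:
    """Annual chronic CVD death rate among CVD survivors."""
    if not cvd_history:
        return 0.0
    tab = values["chronic_cvd_death_female" if female else "chronic_cvd_death_male"]
    return float(tab[age_band_index(age)]) * values["chronic_cvd_death_scale"]


def acute_case_fatality(values: Mapping, age: float) -> float:
    """Probability an incident/recurrent CVD event is acutely fatal."""
    p = values["acute_cf_by_age"][age_band_index(age)] * values["acute_cf_scale"]
    return min(max(p, 0.0), 1.0)


# --------------------------------------------------------------------------
# Cohort-level risk (eligibility screening)
# --------------------------------------------------------------------------

def ten_year_cvd_risk(df: pd.DataFrame, values: Mapping) -> np.ndarray:
    """10-year first-CVD risk at baseline covariates (no treatment change).

    Used by the eligibility filter's elevated-risk criterion.  Integrates the
    summed incident CHD/stroke/HF hazard over 10 years of ageing with
    covariates frozen at baseline; risk = 1 - exp(-cumulative hazard).
    """
    models = build_models(values)
    female = df["female"].to_numpy().astype(bool)
    age0 = df["baseline_age"].to_numpy(dtype=float)
    cum = np.zeros(len(df))
    lps = {o: linear_predictor_df(models[o].coefficients, df) for o in CVD_OUTCOMES}
    for year in range(10):
        ages = age0 + year + 0.5
        for o in CVD_OUTCOMES:
            m = models[o]
            base = np.where(
                female,
                np.asarray(m.baseline_female)[[age_band_index(a) for a in ages]],
                np.asarray(m.baseline_male)[[age_band_index(a) for a in ages]],
            )
            cum += base * np.exp(lps[o]) * values["cvd_hazard_scale"]
    return 1.0 - np.exp(-cum)
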