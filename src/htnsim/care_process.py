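"""Treat-to-target care processes and the four management strategies.

A strategy bundles a BP goal rule, a visit schedule, and care-process
parameters (intensification probability per uncontrolled visit, adherence,
readings per visit) for an intervention window; after the window the care
processes revert to usual care while the BP goal is retained.

Shipped presets:

* ``jnc7_usual``    - usual care, goal <140/90 (or <130/80 with CKD/diabetes,
                      re-evaluated at every visit if either develops mid-run)
* ``sprint_intensive`` - protocolised intensive care: physician visits at
                      months 1, 2, 3 then every 3 months until 3.26 years
                      (median trial follow-up), goal <120/90; usual-care
                      processes afterwards, goal retained
* ``accaha_usual``  - usual care, goal <130/80
* ``tbc``           - team-based care: nonphysician (e.g. pharmacist) visits
                      with titration authority every 6 weeks during year 1,
                      added on top of usual care, goal <130/80; usual care
                      alone afterwards, goal retained
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .config import ConfigurationError

__all__ = [
    "Strategy",
    "MedicationRegimen",
    "BPMeasurement",
    "STRATEGY_PRESETS",
    "get_strategy",
    "bp_goal",
    "next_visit_time",
    "measurement_sd",
    "measure_bp",
    "intensify_decision",
    "apply_titration",
    "apply_adherence",
    "process_params",
    "adherence_at",
]

NO_VISIT = (math.inf, None)


@dataclass(frozen=True)
class Strategy:
    """A treat-to-target management policy."""

    name: str
    goal_kind: str                    # "jnc7" (conditional) or "fixed"
    goal: tuple[float, float]         # (SBP, DBP) mm Hg for goal_kind="fixed"
    protocol: str                     # "usual", "sprint", or "tbc"
    intervention_duration: float      # years of protocolised care
    p_intensify_key: str = "p_intensify_usual"
    adherence_key: str = "adherence_usual"
    readings_key: str = "readings_per_visit_usual"

    def __post_init__(self):
        if self.intervention_duration < 0:
            raise ConfigurationError("intervention_duration must be >= 0")
        if self.goal_kind == "fixed" and not (self.goal[0] > 0 and self.goal[1] > 0):
            raise ConfigurationError("goal pressures must be positive")


STRATEGY_PRESETS: dict[str, Strategy] = {
    "jnc7_usual": Strategy("jnc7_usual", "jnc7", (140.0, 90.0), "usual", 0.0),
    "sprint_intensive": Strategy(
        "sprint_intensive", "fixed", (120.0, 90.0), "sprint", 3.26,
        p_intensify_key="p_intensify_sprint",
        adherence_key="adherence_sprint",
        readings_key="readings_per_visit_sprint"),
    "accaha_usual": Strategy("accaha_usual", "fixed", (130.0, 80.0), "usual", 0.0),
    "tbc": Strategy(
        "tbc", "fixed", (130.0, 80.0), "tbc", 1.0,
        p_intensify_key="p_intensify_tbc",
        adherence_key="adherence_tbc",
        readings_key="readings_per_visit_tbc"),
}

#: Team-based-care nonphysician visit spacing (6 weeks) and window (1 year).
TBC_VISIT_INTERVAL = 6.0 / 52.0
SPRINT_MONTHLY_VISITS = 3


def get_strategy(name: str) -> Strategy:
    try:
        return STRATEGY_PRESETS[name]
    except KeyError:
        raise ConfigurationError(f"unknown strategy {name!r}") from None


# --------------------------------------------------------------------------
# Goals
# --------------------------------------------------------------------------

def bp_goal(strategy: Strategy, state: Mapping) -> tuple[float, float]:
    """The (SBP, DBP) goal for this individual at this moment.

    Re-evaluated at every visit: under the conditional (JNC 7-style) rule the
    goal tightens to <130/80 if CKD or diabetes is present, including when
    either develops during the simulation.
    """
    if strategy.goal_kind == "fixed":
        return strategy.goal
    if strategy.goal_kind == "jnc7":
        if state.get("ckd", 0) or state.get("diabetes", 0):
            return (130.0, 80.0)
        return (140.0, 90.0)
    raise ConfigurationError(f"unknown goal rule {strategy.goal_kind!r}")


# --------------------------------------------------------------------------
# Visit scheduling
# --------------------------------------------------------------------------

def _usual_next(t_now: float, controlled: bool, values: Mapping) -> float:
    iv = values["visit_interval_controlled_yr"] if controlled \
        else values["visit_interval_uncontrolled_yr"]
    return t_now + iv


def _sprint_protocol_next(t_now: float, duration: float) -> float:
    """Months 1, 2, 3 then quarterly, while inside the protocol window."""
    eps = 1e-9
    for m in range(1, SPRINT_MONTHLY_VISITS + 1):
        t = m / 12.0
        if t > t_now + eps:
            return t if t <= duration + eps else math.inf
    # quarterly thereafter
    k = math.floor((t_now - SPRINT_MONTHLY_VISITS / 12.0) / 0.25 + eps) + 1
    t = SPRINT_MONTHLY_VISITS / 12.0 + max(k, 1) * 0.25
    return t if t <= duration + eps else math.inf


def _tbc_next_nonphysician(t_now: float, duration: float) -> float:
    eps = 1e-9
    k = math.floor(t_now / TBC_VISIT_INTERVAL + eps) + 1
    t = k * TBC_VISIT_INTERVAL
    return t if t <= duration + eps else math.inf


def next_visit_time(strategy: Strategy, state: Mapping, t_now: float,
                    values: Mapping, horizon: float = math.inf):
    """Next scheduled encounter after ``t_now``: ``(time, kind)``.

    ``kind`` is ``"physician"`` or ``"nonphysician"``; past-horizon requests
    return the ``(inf, None)`` sentinel.  Usual-care physician intervals are
    state dependent (shorter while BP is uncontrolled at the last visit).
    """
    controlled = bool(state.get("controlled", False))
    candidates: list[tuple[float, str]] = []
    if strategy.protocol == "sprint" and t_now < strategy.intervention_duration - 1e-9:
        t = _sprint_protocol_next(t_now, strategy.intervention_duration)
        if math.isfinite(t):
            candidates.append((t, "physician"))
        else:
            candidates.append((_usual_next(t_now, controlled, values), "physician"))
    else:
        candidates.append((_usual_next(t_now, controlled, values), "physician"))
    if strategy.protocol == "tbc" and t_now < strategy.intervention_duration - 1e-9:
        t = _tbc_next_nonphysician(t_now, strategy.intervention_duration)
        if math.isfinite(t):
            candidates.append((t, "nonphysician"))
    t_best, kind = min(candidates, key=lambda c: c[0])
    if t_best > horizon:
        return NO_VISIT
    return t_best, kind


def process_params(strategy: Strategy, t: float, values: Mapping,
                   visit_kind: str = "physician") -> tuple[float, int]:
    """(intensification probability, readings per visit) for this encounter.

    After the intervention window every strategy uses usual-care values
    exactly; only the goal differs.  Team-based care applies its enhanced
    parameters at nonphysician encounters only (it is *added to* usual care).
    """
    in_intervention = t < strategy.intervention_duration + 1e-9
    if strategy.protocol == "sprint" and in_intervention:
        return values[strategy.p_intensify_key], int(values[strategy.readings_key])
    if strategy.protocol == "tbc" and in_intervention and visit_kind == "nonphysician":
        return values[strategy.p_intensify_key], int(values[strategy.readings_key])
    return values["p_intensify_usual"], int(values["readings_per_visit_usual"])


def adherence_at(strategy: Strategy, t: float, values: Mapping) -> float:
    """Medication adherence (proportion of prescribed effect realised)."""
    if strategy.protocol != "usual" and t < strategy.intervention_duration + 1e-9:
        return values[strategy.adherence_key]
    return values["adherence_usual"]


# --------------------------------------------------------------------------
# Measurement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BPMeasurement:
    measured_sbp: float
    measured_dbp: float
    error_sd: float


def measurement_sd(readings_per_visit: int, visits_so_far: int,
                   values: Mapping) -> float:
    """Effective SD of the visit's working BP estimate.

    Averaging ``r`` readings shrinks the single-reading SD by ``1/sqrt(r)``;
    accumulated visits further shrink it exponentially toward a floor
    (regression of the working estimate toward the truth as information
    accrues).
    """
    sigma0 = values["sigma_base_mmhg"]
    if sigma0 < 0:
        raise ConfigurationError("sigma_base_mmhg must be >= 0")
    if readings_per_visit < 1:
        raise ConfigurationError("readings_per_visit must be >= 1")
    floor = min(values["sigma_floor_mmhg"], sigma0)
    per_visit = sigma0 / math.sqrt(readings_per_visit)
    shrink = math.exp(-values["sigma_visit_decay"] * visits_so_far)
    return floor + max(per_visit - floor, 0.0) * shrink


#: DBP measurement error relative to SBP error (diastolic readings vary less).
DBP_ERROR_RATIO = 0.6


def measure_bp(true_sbp: float, true_dbp: float, readings_per_visit: int,
               visits_so_far: int, rng, values: Mapping) -> BPMeasurement:
    """Unbiased office measurement: truth plus Gaussian error."""
    sd = measurement_sd(readings_per_visit, visits_so_far, values)
    return BPMeasurement(
        measured_sbp=true_sbp + rng.gauss(0.0, sd),
        measured_dbp=true_dbp + rng.gauss(0.0, sd * DBP_ERROR_RATIO),
        error_sd=sd,
    )


def intensify_decision(measurement: BPMeasurement, goal: tuple[float, float],
                       p_intensify: float, rng) -> bool:
    """True = intensify.  Never intensifies when the measured BP is below goal."""
    uncontrolled = (measurement.measured_sbp >= goal[0]
                    or measurement.measured_dbp >= goal[1])
    if not uncontrolled:
        return False
    return rng.random() < p_intensify


# --------------------------------------------------------------------------
# Medication regimen
# --------------------------------------------------------------------------

@dataclass
class MedicationRegimen:
    """Start-low-go-slow titration state.

    Each medication has ``steps_per_med`` dose half-steps; titration raises
    the current medication to full dose before adding the next one.  Baseline
    medications enter at full dose (their effect is already embedded in the
    observed baseline BP), so only ``added_steps`` contribute additional
    lowering.
    """

    n_meds: int
    total_steps: int
    baseline_steps: int
    max_meds: int = 5
    steps_per_med: int = 2

    @classmethod
    def at_baseline(cls, baseline_n_meds: int, max_meds: int = 5,
                    steps_per_med: int = 2) -> "MedicationRegimen":
        steps = baseline_n_meds * steps_per_med
        return cls(baseline_n_meds, steps, steps, max_meds, steps_per_med)

    @property
    def added_steps(self) -> int:
        return self.total_steps - self.baseline_steps

    @property
    def saturated(self) -> bool:
        return (self.n_meds >= self.max_meds
                and self.total_steps >= self.n_meds * self.steps_per_med)


def apply_titration(regimen: MedicationRegimen) -> MedicationRegimen:
    """One titration step: dose up the current medication if not at full
    dose, else add a new medication at a low dose, else no change."""
    if regimen.total_steps < regimen.n_meds * regimen.steps_per_med:
        return replace(regimen, total_steps=regimen.total_steps + 1)
    if regimen.n_meds < regimen.max_meds:
        return replace(regimen, n_meds=regimen.n_meds + 1,
                       total_steps=regimen.total_steps + 1)
    return regimen


def apply_adherence(effect_mm_hg: float, adherence: float) -> float:
    """Realised BP-lowering effect under partial adherence."""
    if not (0.0 <= adherence <= 1.0):
        raise ConfigurationError("adherence must be in [0, 1]")
    return effect_mm_hg * adherence
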