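"""Parameter registry, probabilistic-sensitivity distributions, and RNG plumbing.

Every tunable model input lives in a :class:`ParameterRegistry`: a named entry
with a point value, optional sampling distribution for probabilistic
iterations, units, bounds, and a source note.  Rate *tables* (age-band lookup
tables, per-medication-count tables) are stored as structured values; their
uncertainty is expressed through companion ``*_scale`` multipliers so that a
probabilistic draw shifts a whole table coherently.

Reproducibility: all randomness flows from a single master seed through named
substreams (:func:`substream`), keyed by e.g. ``(iteration, individual,
purpose)``.  Adding a new purpose never perturbs draws of existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import random
import zlib
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "Parameter",
    "ParameterRegistry",
    "ConfigurationError",
    "default_registry",
    "substream",
    "np_substream",
    "registry_hash",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its schema or bounds."""


# --------------------------------------------------------------------------
# RNG substreams
# --------------------------------------------------------------------------

def _key_to_int(key: Any) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf8"))


def substream(master_seed: int, *keys: Any) -> random.Random:
    """A ``random.Random`` deterministically derived from ``(master_seed, *keys)``.

    Keys may be ints or strings (strings are hashed with CRC-32, which is
    stable across platforms and processes).
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    ss = np.random.SeedSequence(entropy)
    return random.Random(int(ss.generate_state(1, dtype=np.uint64)[0]))


def np_substream(master_seed: int, *keys: Any) -> np.random.Generator:
    """Numpy generator variant of :func:`substream` (for vectorised draws)."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

_DIST_FAMILIES = {"beta", "gamma", "lognormal", "normal", "fixed"}


@dataclass
class Parameter:
    """One registry entry.

    ``dist`` is ``None`` (point value only) or a mapping giving a family and
    a dispersion; the distribution is always centred on the *current* point
    value, so probabilistic draws follow a calibrated registry.  Families
    follow standard health-decision-modelling practice: ``beta`` (with
    concentration ``n``) for probabilities, ``gamma`` (with ``shape``) and
    ``lognormal`` (with ``sigma``) for rates and positive multipliers,
    ``normal`` (with ``sd``) for additive effects.
    """

    name: str
    value: Any
    units: str = ""
    source: str = ""
    bounds: tuple[float, float] | None = None
    dist: dict[str, float] | None = None
    note: str = ""

    def validate(self) -> None:
        if self.dist is not None:
            fam = self.dist.get("family")
            if fam not in _DIST_FAMILIES:
                raise ConfigurationError(
                    f"parameter {self.name!r}: unknown distribution family {fam!r}"
                )
            if not isinstance(self.value, (int, float)):
                raise ConfigurationError(
                    f"parameter {self.name!r}: only scalar parameters may carry a "
                    "sampling distribution"
                )
        if self.bounds is not None and isinstance(self.value, (int, float)):
            lo, hi = self.bounds
            if not (lo <= self.value <= hi):
                raise ConfigurationError(
                    f"parameter {self.name!r}: value {self.value} outside bounds "
                    f"[{lo}, {hi}]"
                )

    def draw(self, rng: np.random.Generator) -> Any:
        """One probabilistic draw (point value if no distribution).

        Draws are clipped to ``bounds`` when bounds are set, so probabilistic
        iterations can never wander outside the declared plausible range.
        """
        if self.dist is None:
            return self.value
        fam = self.dist["family"]
        v = float(self.value)
        if fam == "fixed":
            x = v
        elif fam == "beta":
            n = self.dist["n"]
            x = float(rng.beta(max(v, 1e-6) * n, max(1.0 - v, 1e-6) * n))
        elif fam == "gamma":
            shape = self.dist["shape"]
            x = float(rng.gamma(shape, max(v, 1e-12) / shape))
        elif fam == "lognormal":
            sig = self.dist["sigma"]
            x = float(rng.lognormal(np.log(max(v, 1e-12)) - sig**2 / 2.0, sig))
        elif fam == "normal":
            x = float(rng.normal(v, self.dist["sd"]))
        else:  # pragma: no cover - guarded by validate()
            raise ConfigurationError(fam)
        if self.bounds is not None:
            x = float(min(max(x, self.bounds[0]), self.bounds[1]))
        return x


class ParameterRegistry:
    """Mapping of parameter name -> :class:`Parameter` with draw/IO support."""

    def __init__(self, params: Iterable[Parameter] = ()):
        self._params: dict[str, Parameter] = {}
        for p in params:
            self.add(p)

    # -- mapping-ish surface -------------------------------------------------
    def add(self, p: Parameter) -> None:
        p.validate()
        self._params[p.name] = p

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def param(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise ConfigurationError(f"unknown parameter {name!r}") from None

    def get(self, name: str) -> Any:
        return self.param(name).value

    def set(self, name: str, value: Any) -> None:
        p = self.param(name)
        if isinstance(value, np.floating):
            value = float(value)
        elif isinstance(value, np.integer):
            value = int(value)
        p.value = value
        p.validate()

    def copy(self) -> "ParameterRegistry":
        return ParameterRegistry(dataclasses.replace(p) for p in self._params.values())

    def override(self, overrides: Mapping[str, Any]) -> "ParameterRegistry":
        """Copy with ``overrides`` applied; unknown keys are configuration errors."""
        reg = self.copy()
        for k, v in overrides.items():
            reg.set(k, v)
        return reg

    # -- probabilistic iterations ---------------------------------------------
    def draw_values(self, rng: np.random.Generator) -> dict[str, Any]:
        """Point values with every distributed parameter replaced by one draw.

        Iterates in sorted name order so the draw sequence does not depend on
        insertion order.
        """
        out: dict[str, Any] = {}
        for name in sorted(self._params):
            out[name] = self._params[name].draw(rng)
        return out

    def point_values(self) -> dict[str, Any]:
        return {name: p.value for name, p in self._params.items()}

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        out = {}
        for name, p in sorted(self._params.items()):
            d: dict[str, Any] = {"value": p.value}
            if p.units:
                d["units"] = p.units
            if p.source:
                d["source"] = p.source
            if p.bounds is not None:
                d["bounds"] = list(p.bounds)
            if p.dist is not None:
                d["dist"] = dict(p.dist)
            if p.note:
                d["note"] = p.note
            out[name] = d
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterRegistry":
        reg = cls()
        for name, d in data.items():
            if not isinstance(d, Mapping) or "value" not in d:
                raise ConfigurationError(
                    f"registry entry {name!r} must be a mapping with a 'value' key"
                )
            reg.add(
                Parameter(
                    name=name,
                    value=d["value"],
                    units=d.get("units", ""),
                    source=d.get("source", ""),
                    bounds=tuple(d["bounds"]) if "bounds" in d else None,
                    dist=dict(d["dist"]) if "dist" in d else None,
                    note=d.get("note", ""),
                )
            )
        return reg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParameterRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def registry_hash(reg: ParameterRegistry) -> str:
    """Stable SHA-256 of the registry contents (for run manifests)."""
    blob = json.dumps(reg.to_dict(), sort_keys=True, default=float).encode("utf8")
    return hashlib.sha256(blob).hexdigest()


# --------------------------------------------------------------------------
# Default registry
# --------------------------------------------------------------------------

#: Age-band lower edges shared by all age-indexed rate tables (years).
AGE_BANDS = [18, 55, 65, 75, 85]


def _beta(n: float = 100.0) -> dict[str, float]:
    return {"family": "beta", "n": n}


def _lognorm(sigma: float = 0.08) -> dict[str, float]:
    return {"family": "lognormal", "sigma": sigma}


def default_registry() -> ParameterRegistry:
    """The shipped model inputs.

    Hazard-model coefficients and treatment-effect hazard ratios follow the
    published pooled-cohort risk equations and BP-lowering meta-analyses in
    magnitude; care-process parameters marked ``calibrated`` are the free
    parameters the calibration module tunes against the intensive-treatment
    trial targets.  All rates are per person-year unless noted.
    """
    P = Parameter
    params = [
        # ---- care processes --------------------------------------------------
        P("visit_interval_uncontrolled_yr", 0.25, "years",
          "usual-care follow-up when BP uncontrolled", (0.02, 1.0),
          _lognorm(0.15)),
        P("visit_interval_controlled_yr", 0.5, "years",
          "usual-care follow-up when BP controlled", (0.1, 2.0),
          _lognorm(0.15)),
        P("p_intensify_usual", 0.34, "probability per uncontrolled visit",
          "clinical-inertia literature; calibrated", (0.02, 0.8),
          _beta(150)),
        P("p_intensify_sprint", 0.78, "probability per uncontrolled visit",
          "intensive-protocol visit behaviour; calibrated", (0.2, 0.98),
          _beta(150)),
        P("p_intensify_tbc", 0.70, "probability per uncontrolled visit",
          "calibrated to the team-based-care 1-year SBP benchmark", (0.05, 0.98),
          _beta(150)),
        P("adherence_usual", 0.75, "proportion of prescribed effect realised",
          "adherence literature", (0.4, 1.0), _beta(200)),
        P("adherence_sprint", 0.82, "proportion", "trial-protocol support",
          (0.4, 1.0), _beta(200)),
        P("adherence_tbc", 0.82, "proportion", "team-based-care engagement",
          (0.4, 1.0), _beta(200)),
        P("readings_per_visit_usual", 1, "count", "routine single office reading"),
        P("readings_per_visit_sprint", 3, "count", "trial protocol triplicate readings"),
        P("readings_per_visit_tbc", 2, "count", "team-based-care repeated readings"),
        P("sigma_base_mmhg", 9.0, "mm Hg",
          "single-reading office BP measurement SD; calibrated", (3.0, 15.0),
          _lognorm(0.08)),
        P("sigma_floor_mmhg", 2.0, "mm Hg", "residual measurement SD floor", (0.0, 5.0)),
        P("sigma_visit_decay", 0.03, "per cumulative visit",
          "exponential shrinkage of measurement SD as visits accrue", (0.0, 0.5)),
        P("per_step_sbp_mmhg", 8.0, "mm Hg for the first titration step",
          "BP-lowering trial arm contrasts; calibrated", (2.0, 14.0),
          {"family": "normal", "sd": 0.5}),
        P("dose_response_decay", 0.93, "multiplier per successive titration step",
          "diminishing returns of additional agents/doses", (0.7, 1.0)),
        P("dbp_step_ratio", 0.5, "DBP lowering per unit SBP lowering",
          "meta-analytic DBP/SBP effect ratio", (0.2, 0.8)),
        P("max_meds", 5, "count", "maximum antihypertensive medications"),
        P("dose_steps_per_med", 4, "count",
          "dose titration sub-steps per medication (start low, go slow)"),
        P("noshow_prob", 0.0, "probability", "visit non-attendance", (0.0, 1.0)),
        P("deintensify_after_sae", 0, "flag",
          "drop one titration step after a nonfatal SAE (off by default)"),
        # ---- treatment effects ----------------------------------------------
        P("hr_chd_per10", 0.83, "hazard ratio per 10 mm Hg SBP lowering",
          "BP-lowering meta-analysis", (0.5, 1.0), _lognorm(0.03)),
        P("hr_stroke_per10", 0.73, "hazard ratio per 10 mm Hg SBP lowering",
          "BP-lowering meta-analysis", (0.5, 1.0), _lognorm(0.03)),
        P("hr_hf_per10", 0.72, "hazard ratio per 10 mm Hg SBP lowering",
          "BP-lowering meta-analysis", (0.5, 1.0), _lognorm(0.04)),
        P("hr_noncvd_death_per10", 1.0, "hazard ratio per 10 mm Hg SBP lowering",
          "primary analysis assumes no non-CVD-death benefit; scenario flag",
          (0.5, 1.0)),
        P("cvd_hazard_scale", 1.0, "multiplier on incident-CVD baseline hazards",
          "calibrated to trial event rates", (0.2, 4.0), _lognorm(0.05)),
        # ---- adverse events --------------------------------------------------
        P("sae_rate_by_meds", [0.0, 0.0012, 0.0032, 0.0060, 0.0095, 0.0135],
          "per person-year by medication count (0..max_meds)",
          "treatment-related serious adverse events by regimen size"),
        P("sae_rate_scale", 1.0, "multiplier", "", (0.2, 3.0),
          {"family": "gamma", "shape": 25.0}),
        P("iae_rate_by_meds", [0.0, 0.010, 0.020, 0.030, 0.040, 0.050],
          "per person-year by medication count (0..max_meds)",
          "intolerable adverse events prompting a medication switch"),
        P("iae_rate_scale", 1.0, "multiplier", "", (0.2, 3.0),
          {"family": "gamma", "shape": 25.0}),
        P("fatal_sae_prob_by_age", [0.008, 0.012, 0.018, 0.028, 0.045],
          "probability by age band " + str(AGE_BANDS),
          "inpatient-sample case fatality of treatment-related SAEs"),
        P("fatal_sae_scale", 1.0, "multiplier", "", (0.2, 3.0),
          _lognorm(0.15)),
        # ---- event consequence tables ---------------------------------------
        P("acute_cf_by_age", [0.04, 0.065, 0.10, 0.145, 0.24],
          "probability an incident/recurrent CVD event is acutely fatal, by age band",
          "vital-statistics case fatality"),
        P("acute_cf_scale", 1.0, "multiplier", "", (0.2, 3.0),
          _lognorm(0.06)),
        P("chronic_cvd_death_female", [0.0006, 0.0018, 0.0042, 0.010, 0.028],
          "per person-year among CVD survivors, by age band", "vital statistics"),
        P("chronic_cvd_death_male", [0.0009, 0.0026, 0.0060, 0.014, 0.036],
          "per person-year among CVD survivors, by age band", "vital statistics"),
        P("chronic_cvd_death_scale", 1.0, "multiplier", "", (0.2, 3.0),
          _lognorm(0.08)),
        P("recurrent_cvd_female", [0.010, 0.017, 0.027, 0.038, 0.049],
          "recurrent/secondary CVD events per person-year, by age band",
          "inpatient-sample recurrence rates, treated secondary prevention"),
        P("recurrent_cvd_male", [0.013, 0.022, 0.033, 0.045, 0.056],
          "recurrent/secondary CVD events per person-year, by age band",
          "inpatient-sample recurrence rates, treated secondary prevention"),
        P("recurrent_cvd_scale", 1.0, "multiplier", "", (0.2, 3.0),
          _lognorm(0.08)),
        # ---- incident hazards (reference covariate profile) ------------------
        P("h0_chd_female", [0.0006, 0.0020, 0.0042, 0.0085, 0.0150],
          "incident CHD per person-year at reference profile, by age band",
          "pooled-cohort baseline rates"),
        P("h0_chd_male", [0.0012, 0.0036, 0.0070, 0.0130, 0.0220], "", ""),
        P("h0_stroke_female", [0.0002, 0.0008, 0.0019, 0.0048, 0.0105], "", ""),
        P("h0_stroke_male", [0.0003, 0.0010, 0.0022, 0.0055, 0.0115], "", ""),
        P("h0_hf_female", [0.0002, 0.0008, 0.0021, 0.0060, 0.0160], "", ""),
        P("h0_hf_male", [0.0003, 0.0012, 0.0030, 0.0080, 0.0200], "", ""),
        P("h0_noncvd_death_female", [0.0005, 0.0014, 0.0036, 0.0110, 0.0420],
          "non-CVD death per person-year at reference profile, by age band",
          "life tables net of CVD deaths, trial-eligible (healthier) selection"),
        P("h0_noncvd_death_male", [0.0008, 0.0020, 0.0052, 0.0155, 0.0540], "", ""),
        # ---- Cox log-hazard-ratio coefficients -------------------------------
        # Reference profile: never-smoker, SBP 120, BMI 25, no diabetes,
        # HDL 50, LDL 110, eGFR >= 60, non-Black.  Age and sex live in the
        # baseline tables, not the coefficients.
        P("coef_chd", {"smoker": 0.50, "sbp_per10": 0.14, "bmi_per5": 0.06,
                       "diabetes": 0.60, "hdl_per10": -0.15, "ldl_per10": 0.08,
                       "ckd": 0.30, "race_black": -0.10},
          "log hazard ratios", "pooled-cohort equations (representative values)"),
        P("coef_stroke", {"smoker": 0.55, "sbp_per10": 0.25, "bmi_per5": 0.02,
                          "diabetes": 0.50, "hdl_per10": -0.05, "ldl_per10": 0.03,
                          "ckd": 0.30, "race_black": 0.25},
          "log hazard ratios", "pooled-cohort equations (representative values)"),
        P("coef_hf", {"smoker": 0.40, "sbp_per10": 0.20, "bmi_per5": 0.25,
                      "diabetes": 0.70, "hdl_per10": -0.05, "ldl_per10": 0.00,
                      "ckd": 0.40, "race_black": 0.15},
          "log hazard ratios", "pooled-cohort equations (representative values)"),
        P("coef_noncvd_death", {"smoker": 0.80, "sbp_per10": 0.00, "bmi_per5": 0.05,
                                "diabetes": 0.50, "hdl_per10": 0.00,
                                "ldl_per10": 0.00, "ckd": 0.35, "race_black": 0.10},
          "log hazard ratios", "pooled-cohort equations (representative values)"),
        # ---- incident CVD type split governs recurrent-event typing ----------
        P("cvd_type_split", {"chd": 0.55, "stroke": 0.22, "hf": 0.23},
          "proportions", "type split applied to recurrent events"),
        # ---- disability decrements (per year lived with condition) ----------
        P("disability_weights",
          {"acute_cvd": 0.20, "chronic_cvd": 0.07, "iae": 0.02, "sae": 0.10,
           "hypertension": 0.02, "dyslipidemia": 0.01, "obesity": 0.03,
           "diabetes": 0.06, "esrd": 0.25,
           "aging_70": 0.03, "aging_80": 0.08, "aging_90": 0.15},
          "utility decrement per year", "published disability weights"),
        # ---- population / analysis shape ------------------------------------
        P("population_total", 18_100_000.0, "persons",
          "eligible US adults (national weighting total)"),
        P("n_individuals", 25_000, "count", "analysis cohort size (with replacement)"),
        P("n_iterations", 200, "count", "probabilistic iterations"),
        P("horizon_years", 10.0, "years", "fixed analysis horizon"),
        P("max_age", 100.0, "years", "lifetime-horizon age cap"),
    ]
    return ParameterRegistry(params)


def age_band_index(age: float) -> int:
    """Index into AGE_BANDS tables (clamped to the outer bands)."""
    i = 0
    for j, lo in enumerate(AGE_BANDS):
        if age >= lo:
            i = j
    return i
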