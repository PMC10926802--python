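"""The discrete event engine.

Each individual advances event-to-event: office visits (care-process module),
competing clinical events sampled from current hazards (risk-engine module),
annual birthdays (risk-factor trajectory updates), the end of the strategy's
intervention window, and the horizon.  Hazards are piecewise constant between
these state-update boundaries, so candidate event times are exponential draws
that are simply re-drawn (memorylessly) whenever the state changes.

Competing events are resolved by earliest time; exact ties break by fixed
priority (death > CVD > SAE > IAE > visit > birthday > horizon).

For speed, all deterministic per-individual inputs - risk-factor drift on the
annual grid, diabetes/CKD onset, and the full Cox hazard (everything except
the treatment-effect factor) - are precomputed as (individual x year)
matrices when a :class:`CohortSim` is built.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import care_process as cp
from . import risk_engine as re_
from .config import AGE_BANDS, substream
from .outcomes import IterationSummary, healthy_life_years
from .population import TRAJ_AGES, Cohort

__all__ = ["CohortSim", "EventRecord", "select_next", "records_to_dataframe",
           "EVENT_PRIORITY", "CALIBRATION_WINDOW_YEARS"]

EVENT_PRIORITY = {
    "cvd_death": 0, "non_cvd_death": 0, "sae_death": 0,
    "chd": 1, "stroke": 1, "hf": 1, "recurrent_cvd": 1,
    "sae": 2, "iae": 3,
    "physician_visit": 4, "nonphysician_visit": 4,
    "birthday": 5, "intervention_end": 5,
    "horizon_end": 6,
}

#: Window over which trial-calibration statistics (first-event rate,
#: achieved SBP, medication count) are extracted: the trial's median
#: follow-up.
CALIBRATION_WINDOW_YEARS = 3.26


@dataclass(frozen=True)
class EventRecord:
    time: float
    kind: str
    detail: str = ""


def select_next(candidates):
    """Earliest candidate ``(time, kind)``; ties break by EVENT_PRIORITY."""
    if not candidates:
        raise RuntimeError("empty candidate set")
    return min(candidates, key=lambda c: (c[0], EVENT_PRIORITY[c[1]]))


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame([{"time": r.time, "kind": r.kind, "detail": r.detail}
                         for r in records])


def _interp_traj(mat: np.ndarray, rows: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Rowwise linear interpolation of trajectory matrices at continuous ages."""
    a = np.clip(ages, TRAJ_AGES[0], TRAJ_AGES[-1])
    idx = np.clip(np.floor(a).astype(int) - TRAJ_AGES[0], 0, len(TRAJ_AGES) - 2)
    frac = a - (idx + TRAJ_AGES[0])
    return mat[rows, idx] * (1 - frac) + mat[rows, idx + 1] * frac


class CohortSim:
    """One cohort + one parameter draw, ready to simulate any strategy.

    Parameters
    ----------
    cohort : analysis cohort (already weighted and resampled)
    values : parameter mapping (registry point values or one probabilistic draw)
    horizon_years : fixed horizon; ignored when ``lifetime`` is true
    lifetime : simulate to age ``values['max_age']`` or death
    """

    def __init__(self, cohort: Cohort, values: dict, horizon_years: float = 10.0,
                 lifetime: bool = False):
        self.values = values
        self.lifetime = lifetime
        df = cohort.individuals
        self.n = len(df)
        rows = df["traj_row"].to_numpy()
        self.age0 = df["baseline_age"].to_numpy(dtype=float)
        self.female = df["female"].to_numpy(dtype=bool)
        self.clinical_cvd0 = df["clinical_cvd"].to_numpy(dtype=int)
        self.n_meds0 = df["n_meds"].to_numpy(dtype=int)
        self.sbp0 = df["sbp"].to_numpy(dtype=float)
        self.dbp0 = df["dbp"].to_numpy(dtype=float)
        self.dia_onset = df["diabetes_onset_age"].to_numpy(dtype=float)

        if lifetime:
            self.horizon_i = np.maximum(values["max_age"] - self.age0, 0.0)
        else:
            self.horizon_i = np.full(self.n, float(horizon_years))
        K = int(math.floor(self.horizon_i.max() + 1e-9))
        self.K = K

        # deterministic per-year covariates and hazards -----------------------
        years = np.arange(K + 1)
        ages = self.age0[:, None] + years[None, :]            # (n, K+1)
        band = np.digitize(ages, AGE_BANDS[1:], right=False)  # band index per year
        self.band = band
        drift = {}
        for factor in ("sbp", "dbp", "bmi", "hdl", "ldl", "egfr"):
            mat = cohort.trajectories[factor]
            vals = np.empty((self.n, K + 1))
            for kk in range(K + 1):
                vals[:, kk] = _interp_traj(mat, rows, ages[:, kk])
            drift[factor] = vals
        self.sbp_untreated = drift["sbp"]
        self.dbp_untreated = drift["dbp"]
        self.diabetes_active = ages >= self.dia_onset[:, None]
        self.ckd_active = drift["egfr"] < 60.0

        # ESRD onset time (years from baseline), inf if never
        esrd = drift["egfr"] < 15.0
        self.esrd_t = np.where(esrd.any(axis=1),
                               esrd.argmax(axis=1).astype(float), math.inf)
        self.obesity0 = df["bmi"].to_numpy() >= 30.0
        self.dyslip0 = df["ldl"].to_numpy() >= 160.0

        # Cox hazards excluding the treatment-effect factor
        models = re_.build_models(values)
        cvd_scale = values["cvd_hazard_scale"]
        smoker = df["smoker"].to_numpy()
        black = df["race_black"].to_numpy()
        self.haz = {}
        for outcome, model in models.items():
            c = model.coefficients
            lp = (c.get("smoker", 0.0) * smoker[:, None]
                  + c.get("race_black", 0.0) * black[:, None]
                  + c.get("sbp_per10", 0.0) * (np.clip(self.sbp_untreated, 70, 250) - re_.REF["sbp"]) / 10.0
                  + c.get("bmi_per5", 0.0) * (np.clip(drift["bmi"], 12, 80) - re_.REF["bmi"]) / 5.0
                  + c.get("hdl_per10", 0.0) * (np.clip(drift["hdl"], 10, 150) - re_.REF["hdl"]) / 10.0
                  + c.get("ldl_per10", 0.0) * (np.clip(drift["ldl"], 20, 400) - re_.REF["ldl"]) / 10.0
                  + c.get("diabetes", 0.0) * self.diabetes_active
                  + c.get("ckd", 0.0) * self.ckd_active)
            base_f = np.asarray(model.baseline_female)[band]
            base_m = np.asarray(model.baseline_male)[band]
            base = np.where(self.female[:, None], base_f, base_m)
            scale = cvd_scale if outcome in re_.CVD_OUTCOMES else 1.0
            self.haz[outcome] = base * np.exp(lp) * scale

        # per-year secondary tables
        rec_f = np.asarray(values["recurrent_cvd_female"])[band] * values["recurrent_cvd_scale"]
        rec_m = np.asarray(values["recurrent_cvd_male"])[band] * values["recurrent_cvd_scale"]
        self.recurrent_rate = np.where(self.female[:, None], rec_f, rec_m)
        ch_f = np.asarray(values["chronic_cvd_death_female"])[band] * values["chronic_cvd_death_scale"]
        ch_m = np.asarray(values["chronic_cvd_death_male"])[band] * values["chronic_cvd_death_scale"]
        self.chronic_rate = np.where(self.female[:, None], ch_f, ch_m)
        self.acute_cf = np.clip(np.asarray(values["acute_cf_by_age"])[band]
                                * values["acute_cf_scale"], 0.0, 1.0)
        self.fatal_sae = np.clip(np.asarray(values["fatal_sae_prob_by_age"])[band]
                                 * values["fatal_sae_scale"], 0.0, 1.0)
        self.sae_tab = [v * values["sae_rate_scale"] for v in values["sae_rate_by_meds"]]
        self.iae_tab = [v * values["iae_rate_scale"] for v in values["iae_rate_by_meds"]]

        split = values["cvd_type_split"]
        self.split_cum = (split["chd"], split["chd"] + split["stroke"])
        # composite treatment-effect HR exponent weights for recurrent events
        self.split = split

    # ------------------------------------------------------------------
    def run_individual(self, i: int, strategy: cp.Strategy, master_seed: int,
                       iteration: int = 0, keep_records: bool = False):
        """Simulate one individual; returns a result dict.

        RNG substreams are named per (iteration, individual, purpose) so runs
        replay bit-identically and strategies share streams (common random
        numbers).
        """
        v = self.values
        ev = substream(master_seed, iteration, i, "events")
        me = substream(master_seed, iteration, i, "measure")
        de = substream(master_seed, iteration, i, "decide")
        co = substream(master_seed, iteration, i, "consequence")

        horizon = self.horizon_i[i]
        K = self.K
        hr_chd = v["hr_chd_per10"]
        hr_stroke = v["hr_stroke_per10"]
        hr_hf = v["hr_hf_per10"]
        hr_ncd = v["hr_noncvd_death_per10"]
        per_step = v["per_step_sbp_mmhg"]
        rho = v.get("dose_response_decay", 1.0)
        dbp_ratio = v["dbp_step_ratio"]
        split = self.split
        noshow = v["noshow_prob"]
        deintensify = bool(v.get("deintensify_after_sae", 0))

        regimen = cp.MedicationRegimen.at_baseline(
            self.n_meds0[i], int(v["max_meds"]), int(v["dose_steps_per_med"]))
        adh = cp.adherence_at(strategy, 0.0, v)
        history = bool(self.clinical_cvd0[i])
        t = 0.0
        k = 0
        controlled = False
        visits_phys = 0
        visits_nonphys = 0
        counts: dict[str, float] = defaultdict(float)
        records: list[EventRecord] = []
        sbp_year = np.full(K + 1, np.nan)
        dbp_year = np.full(K + 1, np.nan)
        meds_year = np.full(K + 1, np.nan)
        acute_events: list[float] = []   # CVD event times (for HLY decrements)
        sae_times: list[float] = []
        iae_times: list[float] = []
        t_first_cvd = math.inf
        t_history_onset = 0.0 if history else math.inf

        def med_deltas():
            # diminishing dose-response: step s (0-based, counting the
            # baseline regimen) lowers SBP by per_step * rho**s
            b, T = regimen.baseline_steps, regimen.total_steps
            if abs(1.0 - rho) < 1e-9:
                eff = per_step * (T - b)
            else:
                eff = per_step * (rho ** b - rho ** T) / (1.0 - rho)
            d_sbp = eff * adh
            return d_sbp, d_sbp * dbp_ratio

        delta_sbp, delta_dbp = med_deltas()

        def treat_factors(dsbp):
            f_chd = hr_chd ** (dsbp / 10.0)
            f_stroke = hr_stroke ** (dsbp / 10.0)
            f_hf = hr_hf ** (dsbp / 10.0)
            # composite factor for type-agnostic recurrent/chronic rates
            f_comp = math.exp(split["chd"] * math.log(f_chd)
                              + split["stroke"] * math.log(f_stroke)
                              + split["hf"] * math.log(f_hf))
            f_ncd = hr_ncd ** (dsbp / 10.0)
            return f_chd, f_stroke, f_hf, f_comp, f_ncd

        f_chd, f_stroke, f_hf, f_comp, f_ncd = treat_factors(delta_sbp)

        sbp_year[0] = self.sbp_untreated[i, 0] - delta_sbp
        dbp_year[0] = self.dbp_untreated[i, 0] - delta_dbp
        meds_year[0] = regimen.n_meds

        t_phys = 0.0   # everyone presents at a physician visit at baseline
        t_nonphys = (cp._tbc_next_nonphysician(0.0, strategy.intervention_duration)
                     if strategy.protocol == "tbc" else math.inf)
        t_int_end = (strategy.intervention_duration
                     if strategy.intervention_duration > 0 else math.inf)

        alive = True
        cause = None
        while True:
            kk = min(k, K)
            boundary = [(float(k + 1), "birthday"), (t_phys, "physician_visit"),
                        (t_nonphys, "nonphysician_visit"),
                        (t_int_end, "intervention_end"), (horizon, "horizon_end")]
            b_t, b_kind = select_next(boundary)
            best_t, best_kind = b_t, b_kind
            # candidate clinical events under current (piecewise-constant) rates
            if history:
                rates = (("recurrent_cvd", self.recurrent_rate[i, kk] * f_comp),
                         ("cvd_death", self.chronic_rate[i, kk] * f_comp),
                         ("non_cvd_death", self.haz["noncvd_death"][i, kk] * f_ncd),
                         ("sae", self.sae_tab[min(regimen.n_meds, len(self.sae_tab) - 1)]),
                         ("iae", self.iae_tab[min(regimen.n_meds, len(self.iae_tab) - 1)]))
            else:
                rates = (("chd", self.haz["chd"][i, kk] * f_chd),
                         ("stroke", self.haz["stroke"][i, kk] * f_stroke),
                         ("hf", self.haz["hf"][i, kk] * f_hf),
                         ("non_cvd_death", self.haz["noncvd_death"][i, kk] * f_ncd),
                         ("sae", self.sae_tab[min(regimen.n_meds, len(self.sae_tab) - 1)]),
                         ("iae", self.iae_tab[min(regimen.n_meds, len(self.iae_tab) - 1)]))
            for kind, rate in rates:
                if rate > 0.0:
                    te = t + ev.expovariate(rate)
                    if te < best_t:
                        best_t, best_kind = te, kind

            t = best_t
            kind = best_kind

            if kind == "birthday":
                k += 1
                if k <= K:
                    sbp_year[k] = self.sbp_untreated[i, min(k, K)] - delta_sbp
                    dbp_year[k] = self.dbp_untreated[i, min(k, K)] - delta_dbp
                    meds_year[k] = regimen.n_meds
                continue

            if kind == "horizon_end":
                if keep_records:
                    records.append(EventRecord(t, "horizon_end"))
                break

            if kind == "intervention_end":
                t_int_end = math.inf
                adh = cp.adherence_at(strategy, t, v)
                delta_sbp, delta_dbp = med_deltas()
                f_chd, f_stroke, f_hf, f_comp, f_ncd = treat_factors(delta_sbp)
                continue

            if kind in ("physician_visit", "nonphysician_visit"):
                visit_kind = "physician" if kind == "physician_visit" else "nonphysician"
                attended = noshow <= 0.0 or de.random() >= noshow
                if attended:
                    if visit_kind == "physician":
                        visits_phys += 1
                    else:
                        visits_nonphys += 1
                    n_visits = visits_phys + visits_nonphys
                    p_int, readings = cp.process_params(strategy, t, v, visit_kind)
                    true_sbp = self.sbp_untreated[i, kk] - delta_sbp
                    true_dbp = self.dbp_untreated[i, kk] - delta_dbp
                    meas = cp.measure_bp(true_sbp, true_dbp, readings,
                                         n_visits - 1, me, v)
                    state = {"ckd": int(self.ckd_active[i, kk]),
                             "diabetes": int(self.diabetes_active[i, kk])}
                    goal = cp.bp_goal(strategy, state)
                    if cp.intensify_decision(meas, goal, p_int, de):
                        regimen = cp.apply_titration(regimen)
                        adh = cp.adherence_at(strategy, t, v)
                        delta_sbp, delta_dbp = med_deltas()
                        f_chd, f_stroke, f_hf, f_comp, f_ncd = treat_factors(delta_sbp)
                    controlled = (meas.measured_sbp < goal[0]
                                  and meas.measured_dbp < goal[1])
                    if keep_records:
                        records.append(EventRecord(t, kind,
                                                   f"meas={meas.measured_sbp:.1f}"))
                # reschedule
                if visit_kind == "physician":
                    if (strategy.protocol == "sprint"
                            and t < strategy.intervention_duration - 1e-9):
                        t_next = cp._sprint_protocol_next(t, strategy.intervention_duration)
                        if not math.isfinite(t_next):
                            t_next = cp._usual_next(t, controlled, v)
                    else:
                        t_next = cp._usual_next(t, controlled, v)
                    t_phys = t_next
                else:
                    t_nonphys = cp._tbc_next_nonphysician(t, strategy.intervention_duration)
                    # an attended nonphysician titration visit defers the
                    # pending physician follow-up (team-based care reduces
                    # physician burden); the usual state-dependent interval
                    # restarts from this encounter
                    if attended:
                        t_phys = max(t_phys, cp._usual_next(t, controlled, v))
                continue

            if kind in ("chd", "stroke", "hf", "recurrent_cvd"):
                if kind == "recurrent_cvd":
                    u = co.random()
                    etype = ("chd" if u < self.split_cum[0]
                             else "stroke" if u < self.split_cum[1] else "hf")
                    counts["recurrent_cvd"] += 1
                else:
                    etype = kind
                    counts["first_cvd"] += 1
                counts[etype] += 1
                counts["cvd_events"] += 1
                if math.isinf(t_first_cvd):
                    t_first_cvd = t
                acute_events.append(t)
                fatal = co.random() < self.acute_cf[i, kk]
                if keep_records:
                    records.append(EventRecord(t, etype, "fatal" if fatal else "nonfatal"))
                if fatal:
                    counts["cvd_deaths"] += 1
                    counts["acute_cvd_deaths"] += 1
                    counts["deaths_all"] += 1
                    alive = False
                    cause = "cvd_death"
                    break
                if not history:
                    history = True
                    t_history_onset = t
                continue

            if kind == "cvd_death":      # chronic CVD death among survivors
                counts["cvd_deaths"] += 1
                counts["chronic_cvd_deaths"] += 1
                counts["deaths_all"] += 1
                if keep_records:
                    records.append(EventRecord(t, "cvd_death", "chronic"))
                alive = False
                cause = "cvd_death"
                break

            if kind == "non_cvd_death":
                counts["noncvd_deaths"] += 1
                counts["deaths_all"] += 1
                if keep_records:
                    records.append(EventRecord(t, "non_cvd_death"))
                alive = False
                cause = "non_cvd_death"
                break

            if kind == "sae":
                counts["sae"] += 1
                sae_times.append(t)
                if co.random() < self.fatal_sae[i, kk]:
                    counts["sae_deaths"] += 1
                    counts["deaths_all"] += 1
                    if keep_records:
                        records.append(EventRecord(t, "sae", "fatal"))
                    alive = False
                    cause = "sae_death"
                    break
                if deintensify and regimen.added_steps > 0:
                    regimen = cp.MedicationRegimen(
                        regimen.n_meds, regimen.total_steps - 1,
                        regimen.baseline_steps, regimen.max_meds,
                        regimen.steps_per_med)
                    delta_sbp, delta_dbp = med_deltas()
                    f_chd, f_stroke, f_hf, f_comp, f_ncd = treat_factors(delta_sbp)
                if keep_records:
                    records.append(EventRecord(t, "sae", "hospitalization"))
                continue

            if kind == "iae":
                counts["iae"] += 1
                iae_times.append(t)   # medication switched, count unchanged
                if keep_records:
                    records.append(EventRecord(t, "iae", "med_switch"))
                continue

        life_years = t if not alive else horizon

        # calibration-window statistics (first-event rate, person-years)
        w = min(CALIBRATION_WINDOW_YEARS, horizon)
        t_first_stop = min(t_first_cvd, life_years, w)
        counts["py_window"] += t_first_stop
        if t_first_cvd <= t_first_stop:
            counts["first_event_window"] += 1

        # goal attainment at horizon (survivors, true BP vs current goal)
        at_goal = False
        if alive:
            kk = min(int(horizon), K)
            true_sbp = self.sbp_untreated[i, kk] - delta_sbp
            true_dbp = self.dbp_untreated[i, kk] - delta_dbp
            state = {"ckd": int(self.ckd_active[i, kk]),
                     "diabetes": int(self.diabetes_active[i, kk])}
            goal = cp.bp_goal(strategy, state)
            at_goal = true_sbp < goal[0] and true_dbp < goal[1]

        hly = self._hly(i, life_years, t_history_onset, acute_events,
                        sae_times, iae_times)

        return {"counts": dict(counts), "alive": alive, "cause": cause,
                "life_years": life_years, "healthy_life_years": hly,
                "sbp_year": sbp_year, "dbp_year": dbp_year,
                "meds_year": meds_year, "at_goal": at_goal,
                "visits_physician": visits_phys,
                "visits_nonphysician": visits_nonphys,
                "records": records}

    def _hly(self, i, life_years, t_history_onset, acute_events, sae_times,
             iae_times) -> float:
        w = self.values["disability_weights"]
        age0 = self.age0[i]
        intervals = [(0.0, life_years, "hypertension")]
        if self.obesity0[i]:
            intervals.append((0.0, life_years, "obesity"))
        if self.dyslip0[i]:
            intervals.append((0.0, life_years, "dyslipidemia"))
        t_dia = max(0.0, self.dia_onset[i] - age0)
        if t_dia < life_years:
            intervals.append((t_dia, life_years, "diabetes"))
        if self.esrd_t[i] < life_years:
            intervals.append((self.esrd_t[i], life_years, "esrd"))
        for decade, condname in ((70.0, "aging_70"), (80.0, "aging_80"),
                                 (90.0, "aging_90")):
            t0 = decade - age0
            t1 = t0 + 10.0
            if t1 > 0:
                intervals.append((max(t0, 0.0), t1, condname))
        if t_history_onset < life_years:
            intervals.append((t_history_onset, life_years, "chronic_cvd"))
        for te in acute_events:
            intervals.append((te, te + 1.0, "acute_cvd"))
        for te in sae_times:
            intervals.append((te, te + 1.0, "sae"))
        for te in iae_times:
            intervals.append((te, te + 1.0, "iae"))
        return healthy_life_years(intervals, w, life_years)

    # ------------------------------------------------------------------
    def run_cohort(self, strategy: cp.Strategy, master_seed: int,
                   iteration: int = 0) -> IterationSummary:
        """Simulate every individual and aggregate one iteration summary."""
        K = self.K
        counts: dict[str, float] = defaultdict(float)
        sbp_sum = np.zeros(K + 1)
        dbp_sum = np.zeros(K + 1)
        meds_sum = np.zeros(K + 1)
        alive_n = np.zeros(K + 1)
        ly = hly = 0.0
        vp = vn = 0.0
        at_goal = survivors = 0
        for i in range(self.n):
            r = self.run_individual(i, strategy, master_seed, iteration)
            for key, val in r["counts"].items():
                counts[key] += val
            ok = ~np.isnan(r["sbp_year"])
            sbp_sum[ok] += r["sbp_year"][ok]
            dbp_sum[ok] += r["dbp_year"][ok]
            meds_sum[ok] += r["meds_year"][ok]
            alive_n += ok
            ly += r["life_years"]
            hly += r["healthy_life_years"]
            vp += r["visits_physician"]
            vn += r["visits_nonphysician"]
            if r["alive"]:
                survivors += 1
                at_goal += int(r["at_goal"])
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_sbp = np.where(alive_n > 0, sbp_sum / alive_n, np.nan)
            mean_dbp = np.where(alive_n > 0, dbp_sum / alive_n, np.nan)
            mean_meds = np.where(alive_n > 0, meds_sum / alive_n, np.nan)
        return IterationSummary(
            strategy=strategy.name, n=self.n, counts=dict(counts),
            mean_sbp_by_year=mean_sbp, mean_dbp_by_year=mean_dbp,
            mean_meds_by_year=mean_meds, alive_by_year=alive_n,
            goal_attainment=(at_goal / survivors) if survivors else 0.0,
            visits_physician=vp / self.n, visits_nonphysician=vn / self.n,
            life_years=ly / self.n, healthy_life_years=hly / self.n)
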