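"""Turning event streams into reported outcomes.

Outcomes mirror the standard reporting of treat-to-target policy simulations:
events per 1000 individuals over the horizon, annual national event counts
scaled to the eligible population total, undiscounted life years, healthy
life years (life years net of condition-specific disability decrements), and
95% uncertainty intervals from probabilistic iterations (2.5th-97.5th
percentiles of iteration means, linear-interpolation quantile convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError

__all__ = [
    "IterationSummary",
    "per_1000",
    "per_year_national",
    "healthy_life_years",
    "psa_summary",
    "strategy_contrast",
    "summaries_to_frame",
]

#: Event-count keys every IterationSummary carries.
COUNT_KEYS = (
    "chd", "stroke", "hf", "cvd_events", "first_cvd", "recurrent_cvd",
    "cvd_deaths", "acute_cvd_deaths", "chronic_cvd_deaths",
    "sae", "sae_deaths", "iae", "noncvd_deaths", "deaths_all",
    "first_event_window", "py_window",
)


@dataclass
class IterationSummary:
    """Cohort-level results of one (strategy, parameter draw) run."""

    strategy: str
    n: int
    counts: dict[str, float]
    mean_sbp_by_year: np.ndarray          # mean true SBP among survivors, year 0..K
    mean_dbp_by_year: np.ndarray
    mean_meds_by_year: np.ndarray
    alive_by_year: np.ndarray             # survivors at each integer year
    goal_attainment: float                # fraction of survivors at goal at horizon
    visits_physician: float               # mean per individual over horizon
    visits_nonphysician: float
    life_years: float                     # mean undiscounted
    healthy_life_years: float             # mean undiscounted

    def __post_init__(self):
        if self.healthy_life_years > self.life_years + 1e-9:
            raise ValueError("healthy life years cannot exceed life years")
        if not (0.0 <= self.goal_attainment <= 1.0):
            raise ValueError("goal attainment must be a proportion")

    def rate_per_1000(self, key: str) -> float:
        return per_1000(self.counts.get(key, 0.0), self.n)

    def sbp_at(self, t: float) -> float:
        """Mean SBP at a (possibly fractional) year via linear interpolation."""
        years = np.arange(len(self.mean_sbp_by_year))
        return float(np.interp(t, years, self.mean_sbp_by_year))

    def meds_at(self, t: float) -> float:
        years = np.arange(len(self.mean_meds_by_year))
        return float(np.interp(t, years, self.mean_meds_by_year))


def per_1000(count: float, n_individuals: int) -> float:
    """Events per 1000 baseline individuals over the horizon."""
    if n_individuals <= 0:
        raise ConfigurationError("n_individuals must be positive")
    return count * 1000.0 / n_individuals


def per_year_national(count: float, n_individuals: int, population_total: float,
                      horizon_years: float) -> float:
    """Mean annual national events scaled to the eligible population.

    ``(events / baseline individuals / horizon) * population_total``: the
    denominator is the baseline cohort size, matching the "events per year in
    the eligible population" framing rather than person-years alive.
    """
    if horizon_years <= 0:
        raise ConfigurationError("horizon_years must be positive")
    return count / n_individuals / horizon_years * population_total


# --------------------------------------------------------------------------
# Healthy life years
# --------------------------------------------------------------------------

def healthy_life_years(condition_intervals: Sequence[tuple[float, float, str]],
                       weights: Mapping[str, float], life_years: float) -> float:
    """Life years net of disability decrements.

    ``condition_intervals`` lists ``(t_start, t_end, condition)`` periods
    (clipped to ``[0, life_years]``); decrements combine additively within a
    moment, floored at zero, and are integrated over the lived time:
    ``HLY = integral of max(0, 1 - sum active decrements) dt``.
    """
    for _, _, cond in condition_intervals:
        if cond not in weights:
            raise ConfigurationError(f"no disability weight configured for {cond!r}")
        if not (0.0 <= weights[cond] <= 1.0):
            raise ConfigurationError(f"decrement for {cond!r} outside [0, 1]")
    # breakpoints of the piecewise-constant decrement sum
    pts = {0.0, life_years}
    clipped = []
    for t0, t1, cond in condition_intervals:
        t0 = max(0.0, min(t0, life_years))
        t1 = max(0.0, min(t1, life_years))
        if t1 > t0:
            clipped.append((t0, t1, cond))
            pts.update((t0, t1))
    grid = sorted(pts)
    hly = 0.0
    for a, b in zip(grid[:-1], grid[1:]):
        mid = (a + b) / 2.0
        dec = sum(weights[c] for t0, t1, c in clipped if t0 <= mid < t1)
        hly += max(0.0, 1.0 - dec) * (b - a)
    return hly


# --------------------------------------------------------------------------
# Probabilistic summaries
# --------------------------------------------------------------------------

def psa_summary(values: Sequence[float]) -> dict[str, float]:
    """Mean and 95% uncertainty interval across probabilistic iterations.

    UI = empirical 2.5th and 97.5th percentiles of the iteration means,
    linear-interpolation (type-7) quantile convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ConfigurationError("psa_summary needs >= 2 iterations")
    lo, hi = np.percentile(x, [2.5, 97.5], method="linear")
    return {"mean": float(x.mean()), "lo": float(lo), "hi": float(hi)}


def strategy_contrast(values_a: Sequence[float], values_b: Sequence[float]) -> dict[str, float]:
    """Paired (common-random-number) per-iteration difference ``a - b``.

    Differences are formed within iteration, then summarised; iteration sets
    must therefore be paired and equal length.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("strategy contrast requires paired iteration sets")
    return psa_summary(a - b)


def summaries_to_frame(per_strategy: Mapping[str, Sequence[IterationSummary]],
                       horizon_years: float) -> pd.DataFrame:
    """Tidy results table: strategy x outcome x (estimate, lo, hi)."""
    rows = []
    for strategy, its in per_strategy.items():
        n = its[0].n
        series: dict[str, list[float]] = {}
        for s in its:
            series.setdefault("mean_sbp_final", []).append(s.mean_sbp_by_year[-1])
            series.setdefault("goal_attainment_pct", []).append(100 * s.goal_attainment)
            series.setdefault("life_years", []).append(s.life_years)
            series.setdefault("healthy_life_years", []).append(s.healthy_life_years)
            series.setdefault("visits_physician", []).append(s.visits_physician)
            series.setdefault("visits_nonphysician", []).append(s.visits_nonphysician)
            for key in ("cvd_events", "chd", "stroke", "hf", "sae",
                        "deaths_all", "cvd_deaths", "sae_deaths"):
                series.setdefault(f"{key}_per_1000", []).append(s.rate_per_1000(key))
        for outcome, vals in series.items():
            stats = psa_summary(vals) if len(vals) >= 2 else {
                "mean": float(vals[0]), "lo": float(vals[0]), "hi": float(vals[0])}
            rows.append({"strategy": strategy, "outcome": outcome,
                         "estimate": stats["mean"], "lo": stats["lo"],
                         "hi": stats["hi"], "n": n,
                         "horizon_years": horizon_years})
    return pd.DataFrame(rows)
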