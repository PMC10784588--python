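"""Survival curves, median lifespan, and the Mantel-Cox log-rank test.

The product-limit (Kaplan-Meier) estimator and the log-rank test are
implemented directly in the tie-pooled hypergeometric form: deaths recorded
on the same day (the death-check discretization makes ties the norm) are
pooled into a single event time, and at each pooled time j with d_j total
deaths, n_j at risk and n_Aj at risk in group A,

    E_Aj = d_j * n_Aj / n_j
    V_j  = d_j * (n_Aj/n_j) * (1 - n_Aj/n_j) * (n_j - d_j) / (n_j - 1)

with U = sum(d_Aj - E_Aj), chi-square statistic U^2 / sum(V_j) on 1 df.
Times with n_j = 1 contribute zero variance. Right-censored records reduce
the risk set without an event; censoring at a death time is conventionally
processed after the deaths at that time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from flyspan.errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: per event time, risk set, deaths and S(t)."""

    times: np.ndarray  # distinct event (death) times, ascending
    n_risk: np.ndarray  # at risk just before each time
    n_events: np.ndarray  # deaths at each time
    survival: np.ndarray  # S(t) just after each time

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    """Mantel-Cox test summary for two groups (df = 1)."""

    u: float  # observed minus expected deaths in group A
    variance: float
    statistic: float  # U^2 / V; NaN when V = 0
    p_value: float


def _extract(deaths: pd.DataFrame, group=None, diet=None) -> pd.DataFrame:
    sub = deaths
    if group is not None:
        sub = sub[sub["group_id"] == group]
    if diet is not None:
        sub = sub[sub["diet"] == diet]
    return sub


def km_curve(deaths: pd.DataFrame, group=None, diet=None) -> SurvivalCurve:
    """Kaplan-Meier curve for one group (optionally restricted to one diet).

    ``deaths`` has columns group_id, diet, death_day, censored. Censored
    records leave the risk set at their last-observed day without counting
    as events.
    """
    sub = _extract(deaths, group, diet)
    if sub.empty:
        raise AnalysisError(f"no records for group {group!r} (diet {diet!r})")
    days = sub["death_day"].to_numpy(dtype=float)
    censored = sub["censored"].to_numpy(dtype=bool)
    event_times = np.unique(days[~censored])
    n = len(days)
    times, n_risk, n_events, survival = [], [], [], []
    s = 1.0
    for t in event_times:
        # censored at exactly t are still at risk for the deaths at t
        at_risk = int((days > t).sum() + (days == t).sum())
        d = int(((days == t) & ~censored).sum())
        s *= 1.0 - d / at_risk
        times.append(t)
        n_risk.append(at_risk)
        n_events.append(d)
        survival.append(s)
    if not times:
        # all records censored: flat curve at 1 with no event times
        return SurvivalCurve(
            np.array([]), np.array([], int), np.array([], int), np.array([])
        )
    return SurvivalCurve(
        np.array(times),
        np.array(n_risk, dtype=np.int64),
        np.array(n_events, dtype=np.int64),
        np.array(survival),
    )


def median_lifespan(curve: SurvivalCurve) -> float | None:
    """Smallest event time with survival <= 0.5; None (flagged) if never reached.

    No interpolation: with deaths recorded on a coarse check grid the median
    is kept on an observed event time.
    """
    hit = np.flatnonzero(curve.survival <= 0.5)
    if len(hit) == 0:
        warnings.warn("survival never reaches 0.5; median undefined", stacklevel=2)
        return None
    return float(curve.times[hit[0]])


def _days_censored(deaths_or_array) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(deaths_or_array, pd.DataFrame):
        return (
            deaths_or_array["death_day"].to_numpy(dtype=float),
            deaths_or_array["censored"].to_numpy(dtype=bool),
        )
    arr = np.asarray(deaths_or_array, dtype=float)
    return arr, np.zeros(len(arr), dtype=bool)


def logrank_test(deaths_a, deaths_b) -> LogRankResult:
    """Two-sample Mantel-Cox log-rank test.

    Each argument is a death-table DataFrame (columns death_day, censored)
    or a plain array of uncensored death times. Requires at least one event
    per group. Zero pooled variance yields an undefined statistic and p = 1
    with a warning.
    """
    days_a, cens_a = _days_censored(deaths_a)
    days_b, cens_b = _days_censored(deaths_b)
    for name, days, cens in (("A", days_a, cens_a), ("B", days_b, cens_b)):
        if (~cens).sum() == 0:
            raise AnalysisError(f"group {name} has no events")

    days = np.concatenate([days_a, days_b])
    cens = np.concatenate([cens_a, cens_b])
    in_a = np.concatenate(
        [np.ones(len(days_a), dtype=bool), np.zeros(len(days_b), dtype=bool)]
    )
    event_times = np.unique(days[~cens])

    u = 0.0
    var = 0.0
    for t in event_times:
        at_risk = days >= t
        n_j = int(at_risk.sum())
        n_aj = int((at_risk & in_a).sum())
        dead = (days == t) & ~cens
        d_j = int(dead.sum())
        d_aj = int((dead & in_a).sum())
        frac = n_aj / n_j
        u += d_aj - d_j * frac
        if n_j > 1:
            var += d_j * frac * (1.0 - frac) * (n_j - d_j) / (n_j - 1)
    if var == 0.0:
        warnings.warn("zero log-rank variance; statistic undefined", stacklevel=2)
        return LogRankResult(u=u, variance=0.0, statistic=float("nan"), p_value=1.0)
    statistic = u * u / var
    p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(u=u, variance=var, statistic=statistic, p_value=max(p, 0.0))


def survival_report(
    deaths: pd.DataFrame, diet=None, group_col: str = "group_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group median lifespans plus all pairwise log-rank comparisons.

    Groups are ordered by id; the pairwise table has one row per unordered
    pair. Returns ``(medians, pairwise)``.
    """
    sub = deaths if diet is None else deaths[deaths["diet"] == diet]
    groups = sorted(sub[group_col].unique())
    if not groups:
        raise AnalysisError("no groups in death table")
    medians = []
    for g in groups:
        curve = km_curve(sub.rename(columns={group_col: "group_id"}), group=g)
        m = median_lifespan(curve)
        medians.append((g, np.nan if m is None else m))
    medians_df = pd.DataFrame(medians, columns=["group_id", "median_lifespan"])

    rows = []
    for g1, g2 in combinations(groups, 2):
        res = logrank_test(
            sub[sub[group_col] == g1][["death_day", "censored"]],
            sub[sub[group_col] == g2][["death_day", "censored"]],
        )
        rows.append((g1, g2, res.statistic, res.p_value))
    pairwise_df = pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "p_value"]
    )
    return medians_df, pairwise_df
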