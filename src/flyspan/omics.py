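"""Downstream omics statistics: t tests, Storey q-values, DE filter,
Spearman co-abundance screen, and gene-set overlap testing.

Abundances are assumed to be on the log2 scale throughout, so the paired
fold-change of a feature is simply the mean of its per-pair differences
(treated minus control) and pairs naturally with the paired t-test used for
significance. Multiple testing is corrected with Storey q-values: the null
proportion pi0 is estimated on the lambda grid 0, 0.05, ..., 0.90 via
#{p > lambda} / (m (1 - lambda)) and smoothed with a cubic smoothing spline
(three effective degrees of freedom) evaluated at the largest lambda, then
clamped to (0, 1]; q-values are the
step-up-monotone minimum of pi0 * m * p_(j) / j. With pi0 = 1 this reduces
exactly to Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from flyspan.errors import AnalysisError
from flyspan.io import ExpressionMatrix

logger = logging.getLogger(__name__)


def paired_t_test(diffs) -> tuple[float, float]:
    """Two-sided one-sample t test of paired differences against zero.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with n-1 degrees of freedom. Zero
    variance is degenerate: p = 1 if the common difference is 0, else p = 0,
    both logged.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise AnalysisError("need >= 2 paired differences")
    if np.std(d, ddof=1) == 0.0:
        logger.warning("zero-variance paired differences; degenerate p")
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_1samp(d, popmean=0.0)
    return float(t), float(p)


def two_sample_t_test(x, y) -> tuple[float, float]:
    """Two-sided Welch t test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("need >= 2 values per sample")
    if np.std(x, ddof=1) == 0.0 and np.std(y, ddof=1) == 0.0:
        logger.warning("zero variance in both samples; degenerate p")
        return (0.0, 1.0) if x.mean() == y.mean() else (float("inf"), 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


_SPLINE_PENALTY_CACHE: dict[tuple, float] = {}


def _spline_penalty_for_df(x: np.ndarray, target_df: float = 3.0) -> float:
    """Penalty making a cubic smoothing spline on ``x`` have ``target_df``
    effective degrees of freedom (trace of the smoother matrix)."""
    from scipy.interpolate import make_smoothing_spline

    key = (tuple(np.round(x, 12)), target_df)
    if key in _SPLINE_PENALTY_CACHE:
        return _SPLINE_PENALTY_CACHE[key]

    def df(penalty: float) -> float:
        trace = 0.0
        for i in range(len(x)):
            e = np.zeros(len(x))
            e[i] = 1.0
            trace += float(make_smoothing_spline(x, e, lam=penalty)(x[i]))
        return trace

    lo, hi = 1e-8, 1e4
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if df(mid) > target_df:
            lo = mid
        else:
            hi = mid
    penalty = float(np.sqrt(lo * hi))
    _SPLINE_PENALTY_CACHE[key] = penalty
    return penalty


def estimate_pi0(pvals: np.ndarray, lambdas=None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    Computes pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the default
    grid 0, 0.05, ..., 0.90, smooths it with a cubic smoothing spline at
    three effective degrees of freedom, takes the smoother's value at the
    largest lambda, and clamps to (0, 1].
    """
    from scipy.interpolate import make_smoothing_spline

    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        raise AnalysisError("no p-values")
    lam = np.arange(0.0, 0.905, 0.05) if lambdas is None else np.asarray(lambdas)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if len(lam) < 4:
        pi0 = float(pi0_lam[-1])
    else:
        spline = make_smoothing_spline(
            lam, pi0_lam, lam=_spline_penalty_for_df(lam)
        )
        pi0 = float(spline(lam.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; output order matches input order.

    ``pi0=None`` estimates the null proportion with :func:`estimate_pi0`;
    forcing ``pi0=1`` reduces the procedure to Benjamini-Hochberg.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise AnalysisError(f"pi0 must be in (0, 1], got {pi0}")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up monotone
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def differential_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature paired t test with Storey correction.

    Returns a DataFrame with feature_id, log2fc (mean paired difference,
    treated minus control), t_statistic, p, q and unique_peptides. Features
    with fewer than two complete (finite) pairs get NaN statistics and are
    excluded from the q-value computation.
    """
    diffs = matrix.paired_differences()
    rows = []
    for feat in diffs.index:
        d = diffs.loc[feat].to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        if len(d) < 2:
            logger.warning("feature %s has < 2 complete pairs; skipped", feat)
            rows.append((feat, np.nan, np.nan, np.nan))
            continue
        t, p = paired_t_test(d)
        rows.append((feat, float(d.mean()), t, p))
    out = pd.DataFrame(rows, columns=["feature_id", "log2fc", "t_statistic", "p"])
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = storey_qvalues(out.loc[tested, "p"].to_numpy())
    out["unique_peptides"] = matrix.unique_peptides.loc[out["feature_id"]].to_numpy()
    return out


def select_de(
    results: pd.DataFrame,
    min_peptides: int = 2,
    q_max: float = 0.05,
    min_abs_log2fc: float = 0.58,
) -> pd.DataFrame:
    """Significantly changed features by the three-way evidence filter.

    Keeps features with unique_peptides >= min_peptides AND q strictly below
    q_max AND |log2fc| strictly above min_abs_log2fc. Defaults mirror the
    conventional proteomic cutoffs (q < 0.05, |log2FC| > 0.58, >= 2 unique
    peptides).
    """
    keep = (
        (results["unique_peptides"] >= min_peptides)
        & (results["q"] < q_max)
        & (results["log2fc"].abs() > min_abs_log2fc)
    )
    return results[keep.fillna(False)].reset_index(drop=True)


def spearman_screen(
    matrix_or_df,
    target_feature: str,
    rho_min: float = 0.30,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Features whose abundance positively rank-correlates with a target.

    Spearman rho with average ranks for ties, computed on pairwise-complete
    samples; features with fewer than ``min_samples`` overlapping finite
    samples are skipped (count logged). Keeps rho strictly above ``rho_min``
    (one-sided positive screen); the target itself is excluded. Accepts an
    :class:`~flyspan.io.ExpressionMatrix` or a plain feature x sample frame.
    """
    df = (
        matrix_or_df.abundances
        if isinstance(matrix_or_df, ExpressionMatrix)
        else matrix_or_df
    )
    if target_feature not in df.index:
        raise AnalysisError(f"target feature {target_feature!r} not in matrix")
    target = df.loc[target_feature].to_numpy(dtype=float)
    rows = []
    n_skipped = 0
    for feat in df.index:
        if feat == target_feature:
            continue
        vals = df.loc[feat].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(target)
        if ok.sum() < min_samples:
            n_skipped += 1
            continue
        rho = stats.spearmanr(target[ok], vals[ok]).statistic
        if rho > rho_min:
            rows.append((feat, float(rho), int(ok.sum())))
    if n_skipped:
        logger.warning("skipped %d feature(s) with < %d overlapping samples", n_skipped, min_samples)
    return pd.DataFrame(rows, columns=["feature_id", "rho", "n_samples"])


@dataclass
class OverlapResult:
    """Hypergeometric enrichment of the intersection of two gene sets."""

    size_a: int
    size_b: int
    universe_size: int
    overlap: int
    p_value: float  # upper-tail P(X >= overlap)
    fold_enrichment: float  # overlap / expected overlap


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """One-sided hypergeometric test of gene-set overlap.

    Both sets must be subsets of the explicit universe (no default universe
    is assumed); violations raise with the offending ids named. The p-value
    is P(X >= k) for X hypergeometric with N = |universe|, K = |A|,
    n = |B|.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    for name, s in (("A", set_a), ("B", set_b)):
        stray = s - universe
        if stray:
            shown = ", ".join(sorted(stray)[:5])
            raise AnalysisError(
                f"set {name} has {len(stray)} id(s) outside the universe: {shown}"
            )
    n_universe, n_a, n_b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, n_universe, n_a, n_b))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    expected = n_a * n_b / n_universe if n_universe else np.nan
    fold = k / expected if expected else np.nan
    return OverlapResult(
        size_a=n_a,
        size_b=n_b,
        universe_size=n_universe,
        overlap=k,
        p_value=p,
        fold_enrichment=fold,
    )
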