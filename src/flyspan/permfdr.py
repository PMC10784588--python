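"""Permutation-based empirical FDR for the extreme-phenotype scan.

For each permutation i the per-line median lifespans on the analyzed diet
are shuffled across line ids, the in-case/non-case split is re-assigned on
the shuffled phenotypes, and every marker is re-tested with Fisher's exact
test. With n_i(t) the number of markers reaching nominal p <= t in
permutation i and n_real(t) the same count in the real data,

    FDR(t) = mean_i n_i(t) / n_real(t),

capped at 1 and left undefined (not 0) where n_real(t) = 0. Ten
permutations are the default. Re-assigning the dichotomization inside every
permutation is essential: it propagates the selection of extremes into the
null distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from flyspan.association import CaseAssignment, assign_cases, run_association
from flyspan.errors import AnalysisError
from flyspan.io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default p-value threshold grid for the FDR curve.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 5e-2)


def validate_thresholds(thresholds) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise AnalysisError("threshold grid must be a non-empty 1-D sequence")
    if not ((t > 0) & (t < 1)).all():
        raise AnalysisError("thresholds must lie strictly in (0, 1)")
    if not (np.diff(t) > 0).all():
        raise AnalysisError("thresholds must be strictly increasing")
    return t


@dataclass
class FDRCurve:
    """Empirical FDR per threshold, with the permutation audit trail.

    ``table`` has columns t, n_real, mean_null, fdr, defined; ``null_counts``
    is the (n_perm x n_thresholds) array of n_i(t); ``results`` is the
    real-data association table the curve was computed from.
    """

    table: pd.DataFrame
    null_counts: np.ndarray
    results: pd.DataFrame
    n_perm: int
    seed: int

    def fdr_at(self, t: float) -> float:
        row = self.table[self.table["t"] == t]
        if row.empty:
            raise KeyError(f"threshold {t} not on the grid")
        return float(row["fdr"].iloc[0])


def permute_phenotypes(
    phenotypes: pd.DataFrame,
    diet: str,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Shuffle median lifespans across lines within one diet.

    Rows of other diets are untouched; the multiset of lifespans on the
    permuted diet is preserved exactly.
    """
    if (phenotypes["diet"] == diet).sum() < 2:
        raise AnalysisError(f"need >= 2 lines phenotyped on {diet!r} to permute")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = phenotypes.copy()
    mask = out["diet"] == diet
    values = out.loc[mask, "median_lifespan"].to_numpy()
    out.loc[mask, "median_lifespan"] = rng.permutation(values)
    return out


def _count_at_thresholds(pvals: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    return (pvals[:, None] <= thresholds[None, :]).sum(axis=0)


def estimate_fdr(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    diet: str = "DR",
    assign_params: dict | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    n_perm: int = 10,
    seed: int = 0,
    _identity_permutations: bool = False,
) -> FDRCurve:
    """Run the real scan plus ``n_perm`` permuted scans and tabulate FDR(t).

    ``assign_params`` are forwarded to :func:`flyspan.association.assign_cases`
    (mode, top_k, lifespan_threshold). Permutation i draws from an
    independent substream ``SeedSequence([seed, i])`` so the run is
    deterministic and parallelizable. ``_identity_permutations`` is a test
    hook that skips the shuffle (FDR must then be exactly 1 wherever
    defined).
    """
    if n_perm < 1:
        raise AnalysisError("n_perm must be >= 1")
    thresholds = validate_thresholds(thresholds)
    assign_params = dict(assign_params or {})

    real_cases = assign_cases(phenotypes, diet=diet, **assign_params)
    results = run_association(genotypes, real_cases)
    n_real = _count_at_thresholds(results["p_nominal"].to_numpy(), thresholds)

    null_counts = np.zeros((n_perm, len(thresholds)), dtype=np.int64)
    for i in range(n_perm):
        if _identity_permutations:
            permuted = phenotypes
        else:
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            permuted = permute_phenotypes(phenotypes, diet, rng)
        perm_cases = assign_cases(permuted, diet=diet, **assign_params)
        perm_results = run_association(genotypes, perm_cases)
        null_counts[i] = _count_at_thresholds(
            perm_results["p_nominal"].to_numpy(), thresholds
        )

    mean_null = null_counts.mean(axis=0)
    defined = n_real > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(defined, np.minimum(mean_null / np.maximum(n_real, 1), 1.0), np.nan)
    if not defined.any():
        warnings.warn(
            "no threshold has real discoveries; FDR undefined everywhere",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "t": thresholds,
            "n_real": n_real,
            "mean_null": mean_null,
            "fdr": fdr,
            "defined": defined,
        }
    )
    return FDRCurve(
        table=table,
        null_counts=null_counts,
        results=results,
        n_perm=n_perm,
        seed=seed,
    )


def call_significant(
    results: pd.DataFrame, curve: FDRCurve, fdr_max: float
) -> set[str]:
    """Markers with nominal p <= t*, the largest threshold with FDR <= fdr_max.

    Returns the empty set when no threshold qualifies.
    """
    tab = curve.table
    ok = tab["defined"] & (tab["fdr"] <= fdr_max)
    if not ok.any():
        return set()
    t_star = float(tab.loc[ok, "t"].max())
    hit = results["p_nominal"].to_numpy() <= t_star
    return set(results.loc[hit, "marker_id"])


def monotonize_fdr(curve: FDRCurve) -> FDRCurve:
    """Optional step-down: running minimum of FDR from the largest t down.

    Not applied by default; provided for sensitivity analysis.
    """
    tab = curve.table.copy()
    vals = tab["fdr"].to_numpy(copy=True)
    best = np.inf
    for i in range(len(vals) - 1, -1, -1):
        if np.isnan(vals[i]):
            continue
        best = min(best, vals[i])
        vals[i] = best
    tab["fdr"] = vals
    return FDRCurve(
        table=tab,
        null_counts=curve.null_counts,
        results=curve.results,
        n_perm=curve.n_perm,
        seed=curve.seed,
    )
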