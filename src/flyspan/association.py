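"""Extreme-phenotype marker association for inbred line panels.

Lines are dichotomized on one diet into an in-case group (the longest-lived
lines) and a non-case group, and each marker's genotype split is tested with
a two-sided Fisher's exact test on the contingency table

    [[case_ref, case_alt],
     [noncase_ref, noncase_alt]]

Two dichotomization modes are provided because either reading of the design
is defensible: ``top_k`` (default; the k longest-lived lines are in-case)
and ``threshold`` (lines with median lifespan strictly above a cutoff are
in-case). Missing genotype calls are excluded per marker, so each table
counts only labeled lines with an observed homozygous call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from flyspan.errors import AnalysisError
from flyspan.io import ALT, REF, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class CaseAssignment:
    """Which lines are in-case, plus the parameters that produced the split."""

    in_case: frozenset[str]
    non_case: frozenset[str]
    diet: str
    mode: str
    top_k: int | None = None
    lifespan_threshold: float | None = None

    @property
    def labeled_lines(self) -> frozenset[str]:
        return self.in_case | self.non_case


@dataclass(frozen=True)
class ContingencyTable:
    """Fixed-layout 2x2 genotype table: rows in-case/non-case, cols REF/ALT."""

    case_ref: int
    case_alt: int
    noncase_ref: int
    noncase_alt: int

    def __post_init__(self) -> None:
        if min(self.case_ref, self.case_alt, self.noncase_ref, self.noncase_alt) < 0:
            raise AnalysisError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.case_ref, self.case_alt], [self.noncase_ref, self.noncase_alt]]
        )

    @property
    def total(self) -> int:
        return self.case_ref + self.case_alt + self.noncase_ref + self.noncase_alt


def assign_cases(
    phenotypes: pd.DataFrame,
    diet: str = "DR",
    mode: str = "top_k",
    top_k: int = 25,
    lifespan_threshold: float = 41.0,
) -> CaseAssignment:
    """Split phenotyped lines into in-case and non-case groups on one diet.

    ``top_k`` mode marks the k lines with the greatest median lifespan as
    in-case, ties at the k-th value broken by ascending line id so the split
    is deterministic. ``threshold`` mode marks lines with median strictly
    above ``lifespan_threshold`` (days) as in-case.
    """
    sub = phenotypes.loc[phenotypes["diet"] == diet, ["line_id", "median_lifespan"]]
    if sub["line_id"].duplicated().any():
        raise AnalysisError(f"duplicate line ids phenotyped on diet {diet!r}")
    if mode == "top_k":
        if len(sub) < top_k:
            raise AnalysisError(
                f"top_k={top_k} but only {len(sub)} lines phenotyped on {diet}"
            )
        ranked = sub.sort_values(
            ["median_lifespan", "line_id"], ascending=[False, True]
        )
        in_case = frozenset(ranked["line_id"].iloc[:top_k])
        return CaseAssignment(
            in_case=in_case,
            non_case=frozenset(sub["line_id"]) - in_case,
            diet=diet,
            mode=mode,
            top_k=top_k,
        )
    if mode == "threshold":
        in_case = frozenset(
            sub.loc[sub["median_lifespan"] > lifespan_threshold, "line_id"]
        )
        if not in_case:
            warnings.warn(
                f"no line exceeds {lifespan_threshold} days on {diet}; "
                "in-case group is empty",
                stacklevel=2,
            )
        return CaseAssignment(
            in_case=in_case,
            non_case=frozenset(sub["line_id"]) - in_case,
            diet=diet,
            mode=mode,
            lifespan_threshold=lifespan_threshold,
        )
    raise AnalysisError(f"unknown dichotomization mode {mode!r}")


def build_table(
    genotypes: GenotypeMatrix, marker_id: str, cases: CaseAssignment
) -> ContingencyTable:
    """Count REF/ALT calls per group at one marker; missing calls drop out."""
    j = genotypes.marker_index(marker_id)
    col = genotypes.calls[:, j]
    case_mask = np.fromiter(
        (line in cases.in_case for line in genotypes.line_ids),
        dtype=bool,
        count=genotypes.n_lines,
    )
    noncase_mask = np.fromiter(
        (line in cases.non_case for line in genotypes.line_ids),
        dtype=bool,
        count=genotypes.n_lines,
    )
    return ContingencyTable(
        case_ref=int(((col == REF) & case_mask).sum()),
        case_alt=int(((col == ALT) & case_mask).sum()),
        noncase_ref=int(((col == REF) & noncase_mask).sum()),
        noncase_alt=int(((col == ALT) & noncase_mask).sum()),
    )


@lru_cache(maxsize=1 << 20)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p by the minimum-likelihood rule.

    Sums, over all tables with the observed margins, the hypergeometric
    point probabilities that do not exceed the observed table's probability
    (SciPy's two-sided convention). An all-zero table returns p = 1.
    """
    if table.total == 0:
        logger.warning("all-zero contingency table; returning p = 1")
        return 1.0
    p = _fisher_p(table.case_ref, table.case_alt, table.noncase_ref, table.noncase_alt)
    return min(p, 1.0)


def run_association(
    genotypes: GenotypeMatrix, cases: CaseAssignment
) -> pd.DataFrame:
    """Fisher's exact test at every marker, in input marker order.

    Returns a DataFrame with one row per marker: marker_id, contig, position
    (when coordinates are present), the four table counts, and p_nominal.
    Genotyped lines without a phenotype label are excluded with a logged
    count; labeled lines without genotypes simply never enter any table.
    """
    line_arr = np.array(genotypes.line_ids, dtype=object)
    case_mask = np.isin(line_arr, list(cases.in_case))
    noncase_mask = np.isin(line_arr, list(cases.non_case))
    n_unlabeled = int((~case_mask & ~noncase_mask).sum())
    if n_unlabeled:
        logger.info("excluding %d genotyped but unphenotyped line(s)", n_unlabeled)

    calls = genotypes.calls
    case_ref = ((calls == REF) & case_mask[:, None]).sum(axis=0)
    case_alt = ((calls == ALT) & case_mask[:, None]).sum(axis=0)
    noncase_ref = ((calls == REF) & noncase_mask[:, None]).sum(axis=0)
    noncase_alt = ((calls == ALT) & noncase_mask[:, None]).sum(axis=0)

    pvals = np.fromiter(
        (
            1.0
            if (a + b + c + d) == 0
            else min(_fisher_p(int(a), int(b), int(c), int(d)), 1.0)
            for a, b, c, d in zip(case_ref, case_alt, noncase_ref, noncase_alt)
        ),
        dtype=float,
        count=genotypes.n_markers,
    )
    out = {
        "marker_id": genotypes.marker_ids,
        "case_ref": case_ref,
        "case_alt": case_alt,
        "noncase_ref": noncase_ref,
        "noncase_alt": noncase_alt,
        "p_nominal": pvals,
    }
    if genotypes.has_coordinates():
        out = {
            "marker_id": genotypes.marker_ids,
            "contig": genotypes.contigs,
            "position": genotypes.positions,
            **{k: v for k, v in out.items() if k != "marker_id"},
        }
    return pd.DataFrame(out)


def annotate_markers(
    results: pd.DataFrame, intervals: pd.DataFrame
) -> pd.DataFrame:
    """Label each marker with the genes whose interval contains its position.

    Intervals are 1-based inclusive on both ends. Markers inside no gene get
    an empty ``gene_ids`` string (intergenic); results without coordinate
    columns are returned unchanged with a warning.
    """
    if "contig" not in results.columns or "position" not in results.columns:
        warnings.warn("results carry no coordinates; skipping annotation", stacklevel=2)
        return results
    out = results.copy()
    gene_ids = []
    by_contig = {c: g for c, g in intervals.groupby("contig")}
    for row in out.itertuples(index=False):
        genes = by_contig.get(row.contig)
        if genes is None:
            gene_ids.append("")
            continue
        hit = genes[(genes["start"] <= row.position) & (row.position <= genes["end"])]
        gene_ids.append(",".join(hit["gene_id"]))
    out["gene_ids"] = gene_ids
    return out
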