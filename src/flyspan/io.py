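"""Readers, writers and containers for the pipeline's tabular formats.

All genotype calls are homozygous: inbred panel lines are (near-)fully
homozygous, so each call is reference-homozygous, alternate-homozygous or
missing. Heterozygous VCF genotypes are treated as missing rather than
rejected, which tolerates residual heterozygosity in real call sets while
keeping the analysis homozygous-only.

Conventions
-----------
* Genotype TSV: header row of marker ids, first column ``line_id``, cells in
  ``{0, 2, NA}`` (0 = REF hom, 2 = ALT hom, NA = missing). Optional marker
  coordinates travel in leading ``#contig`` / ``#position`` comment lines.
* Internal coordinates are 1-based inclusive (GFF convention); BED is
  converted at the boundary.
* Phenotype CSV columns: ``line_id,diet,median_lifespan``; death CSV columns:
  ``group_id,diet,death_day,censored``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from flyspan.errors import FormatError

logger = logging.getLogger(__name__)

#: Genotype call codes stored in :class:`GenotypeMatrix.calls`.
REF: int = 0
ALT: int = 2
MISSING: int = -1

DIETS = ("AL", "DR")

_TSV_TOKEN = {"0": REF, "2": ALT, "NA": MISSING}
_TOKEN_TSV = {REF: "0", ALT: "2", MISSING: "NA"}


@dataclass
class GenotypeMatrix:
    """Homozygous biallelic calls for L lines x M markers.

    ``calls`` holds :data:`REF` / :data:`ALT` / :data:`MISSING` codes as an
    ``int8`` array of shape ``(L, M)``. ``contigs``/``positions`` (1-based),
    when present, align with ``marker_ids``.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    contigs: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        for name, ids in (("line", self.line_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(f"duplicate {name} id(s): {', '.join(dup)}")
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid call code {self.calls[r, c]} at line "
                f"{self.line_ids[r]!r}, marker {self.marker_ids[c]!r}"
            )
        if (self.contigs is None) != (self.positions is None):
            raise FormatError("contigs and positions must be given together")
        if self.contigs is not None:
            self.contigs = np.asarray(self.contigs, dtype=object)
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if len(self.contigs) != len(self.marker_ids) or len(
                self.positions
            ) != len(self.marker_ids):
                raise FormatError("marker coordinates do not align with marker ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def has_coordinates(self) -> bool:
        return self.contigs is not None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in matrix") from None

    def select_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        """New matrix with the marker columns at ``indices`` (order kept)."""
        indices = np.asarray(indices, dtype=np.intp)
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in indices],
            calls=self.calls[:, indices],
            contigs=None if self.contigs is None else self.contigs[indices],
            positions=None if self.positions is None else self.positions[indices],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_coords = (
            self.contigs is None
            and other.contigs is None
            or (
                self.contigs is not None
                and other.contigs is not None
                and list(self.contigs) == list(other.contigs)
                and np.array_equal(self.positions, other.positions)
            )
        )
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
            and same_coords
        )


# ---------------------------------------------------------------------------
# Genotype TSV
# ---------------------------------------------------------------------------


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write a genotype TSV (cells 0/2/NA; coords as #-comment lines)."""
    with open(path, "w") as fh:
        if matrix.has_coordinates():
            fh.write("\t".join(["#contig", *map(str, matrix.contigs)]) + "\n")
            fh.write("\t".join(["#position", *map(str, matrix.positions)]) + "\n")
        fh.write("\t".join(["line_id", *matrix.marker_ids]) + "\n")
        for i, line_id in enumerate(matrix.line_ids):
            cells = [_TOKEN_TSV[c] for c in matrix.calls[i]]
            fh.write("\t".join([line_id, *cells]) + "\n")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_genotypes_tsv`."""
    contigs = positions = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    while lines and lines[0].startswith("#"):
        key, *vals = lines.pop(0).split("\t")
        if key == "#contig":
            contigs = np.array(vals, dtype=object)
        elif key == "#position":
            try:
                positions = np.array([int(v) for v in vals], dtype=np.int64)
            except ValueError as exc:
                raise FormatError(f"non-integer position in header: {exc}") from None
        else:
            logger.warning("ignoring unknown comment line %r", key)
    if not lines:
        raise FormatError(f"{path}: no header row")
    header = lines[0].split("\t")
    marker_ids = header[1:]
    n_markers = len(marker_ids)
    line_ids: list[str] = []
    calls = np.empty((len(lines) - 1, n_markers), dtype=np.int8)
    for r, raw in enumerate(lines[1:]):
        cells = raw.split("\t")
        if len(cells) != n_markers + 1:
            raise FormatError(
                f"row {r + 2} ({cells[0]!r}): expected {n_markers + 1} columns, "
                f"got {len(cells)}"
            )
        line_ids.append(cells[0])
        for c, tok in enumerate(cells[1:]):
            try:
                calls[r, c] = _TSV_TOKEN[tok]
            except KeyError:
                raise FormatError(
                    f"row {r + 2}, column {marker_ids[c]!r}: unknown cell "
                    f"token {tok!r} (expected 0, 2 or NA)"
                ) from None
    return GenotypeMatrix(line_ids, marker_ids, calls, contigs, positions)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read homozygous calls from a VCF.

    ``0/0`` maps to REF, ``1/1`` (phased or not) to ALT; missing and
    heterozygous genotypes map to MISSING. Multi-allelic records are skipped
    with a warning. Positions are stored 1-based as in the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    contigs: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic record %s:%d", variant.CHROM, variant.POS
            )
            continue
        col = np.full(len(line_ids), MISSING, dtype=np.int8)
        for s, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a == 0 and b == 0:
                col[s] = REF
            elif a == 1 and b == 1:
                col[s] = ALT
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        contigs.append(variant.CHROM)
        positions.append(variant.POS)
        columns.append(col)
    vcf.close()
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(line_ids), 0), dtype=np.int8)
    )
    if n_skipped:
        logger.warning("skipped %d multi-allelic record(s)", n_skipped)
    return GenotypeMatrix(
        line_ids,
        marker_ids,
        calls,
        np.array(contigs, dtype=object),
        np.array(positions, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Marker statistics and filtering
# ---------------------------------------------------------------------------


def compute_marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker minor-allele frequency and call rate.

    MAF is computed over non-missing lines only and folded to [0, 0.5];
    all-missing markers get ``call_rate`` 0 and undefined (NaN) MAF.
    """
    calls = matrix.calls
    n_lines = max(matrix.n_lines, 1)
    n_alt = (calls == ALT).sum(axis=0)
    n_obs = (calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(n_obs > 0, n_alt / np.maximum(n_obs, 1), np.nan)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    return pd.DataFrame(
        {
            "marker_id": matrix.marker_ids,
            "maf": maf,
            "call_rate": n_obs / n_lines,
        }
    )


def filter_markers(
    matrix: GenotypeMatrix,
    stats: pd.DataFrame | None = None,
    maf_min: float = 0.25,
    min_call_rate: float = 0.0,
) -> GenotypeMatrix:
    """Keep markers with ``maf >= maf_min`` and ``call_rate >= min_call_rate``.

    Marker order is preserved. Markers with undefined MAF (no observed
    calls) are dropped. The 0.25 default mirrors the panel's common-variant
    filter, chosen so the minor allele is carried by many lines.
    """
    if stats is None:
        stats = compute_marker_stats(matrix)
    if list(stats["marker_id"]) != matrix.marker_ids:
        raise AnalysisMismatch("marker stats are not aligned with the matrix")
    maf = stats["maf"].to_numpy()
    keep = (
        ~np.isnan(maf)
        & (maf >= maf_min)
        & (stats["call_rate"].to_numpy() >= min_call_rate)
    )
    return matrix.select_markers(np.flatnonzero(keep))


class AnalysisMismatch(FormatError):
    """Inputs that should describe the same markers/lines do not align."""


# ---------------------------------------------------------------------------
# Phenotypes and deaths
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {', '.join(missing)}")


def read_phenotypes_csv(path) -> pd.DataFrame:
    """Per-line median lifespan by diet: columns line_id, diet, median_lifespan."""
    df = pd.read_csv(path, dtype={"line_id": str})
    _require_columns(df, ("line_id", "diet", "median_lifespan"), str(path))
    bad_diet = ~df["diet"].isin(DIETS)
    if bad_diet.any():
        row = df.index[bad_diet][0]
        raise FormatError(
            f"{path}: row {row + 2}: diet {df.loc[row, 'diet']!r} not in {DIETS}"
        )
    if (df["median_lifespan"] <= 0).any():
        row = df.index[df["median_lifespan"] <= 0][0]
        raise FormatError(f"{path}: row {row + 2}: non-positive median lifespan")
    if df.duplicated(["line_id", "diet"]).any():
        dup = df[df.duplicated(["line_id", "diet"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate (line_id, diet) pair ({dup['line_id']}, {dup['diet']})"
        )
    return df


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_deaths_csv(path) -> pd.DataFrame:
    """Individual death records: columns group_id, diet, death_day, censored."""
    df = pd.read_csv(path, dtype={"group_id": str})
    _require_columns(df, ("group_id", "diet", "death_day", "censored"), str(path))
    if (df["death_day"] <= 0).any():
        row = df.index[df["death_day"] <= 0][0]
        raise FormatError(f"{path}: row {row + 2}: non-positive death_day")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_deaths_csv(deaths: pd.DataFrame, path) -> None:
    out = deaths.copy()
    out["censored"] = out["censored"].astype(int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene lists and intervals
# ---------------------------------------------------------------------------


def read_gene_list(path) -> list[str]:
    """One gene id per line; blanks skipped; de-duplicated, order preserved."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for raw in fh:
            gene = raw.strip()
            if gene:
                seen.setdefault(gene, None)
    return list(seen)


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")


def read_gene_intervals(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open) or GFF3 (1-based inclusive).

    Normalized internally to 1-based inclusive coordinates. Returns columns
    gene_id, contig, start, end.
    """
    path = str(path)
    if path.endswith(".bed"):
        return _read_bed(path)
    if path.endswith((".gff", ".gff3")):
        return _read_gff(path)
    raise FormatError(f"{path}: unrecognized interval format (want .bed/.gff/.gff3)")


def _read_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {i}: BED needs >=4 columns (name)")
            contig, start, end, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}: line {i}: non-integer coordinate") from None
            if end_i <= start_i:
                raise FormatError(f"{path}: line {i}: empty or inverted interval")
            rows.append((name, contig, start_i + 1, end_i))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end"])


def _read_gff(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {i}: GFF needs 9 columns")
            contig, _, _, start, end, _, _, _, attrs = fields[:9]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}: line {i}: non-integer coordinate") from None
            if end_i < start_i:
                raise FormatError(f"{path}: line {i}: end < start")
            gene_id = None
            for attr in attrs.split(";"):
                key, _, value = attr.strip().partition("=")
                if key in ("ID", "Name", "gene_id"):
                    gene_id = value
                    break
            if gene_id is None:
                raise FormatError(f"{path}: line {i}: no ID/Name attribute")
            rows.append((gene_id, contig, start_i, end_i))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end"])


def write_gene_intervals_bed(intervals: pd.DataFrame, path) -> None:
    """Write internal 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start - 1}\t{row.end}\t{row.gene_id}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Feature x sample log2 abundances with pairing metadata.

    ``samples`` has one row per sample id with columns ``condition``
    (``"treated"``/``"control"``) and ``pair_id``; ``unique_peptides`` is
    indexed by feature id. Pairs are complete: each pair id occurs once per
    condition.
    """

    abundances: pd.DataFrame
    samples: pd.DataFrame
    unique_peptides: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.abundances.columns) != list(self.samples.index):
            raise FormatError("sample metadata does not align with abundance columns")
        if self.unique_peptides is None:
            self.unique_peptides = pd.Series(
                2, index=self.abundances.index, name="unique_peptides"
            )
        if not self.unique_peptides.index.equals(self.abundances.index):
            raise FormatError("unique_peptides index does not match feature ids")
        counts = self.samples.groupby(["pair_id", "condition"]).size()
        if (counts != 1).any():
            raise FormatError("pairing is incomplete or duplicated")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundances.index)

    def paired_differences(self) -> pd.DataFrame:
        """Feature x pair matrix of treated-minus-control log2 differences."""
        meta = self.samples
        pairs = sorted(meta["pair_id"].unique())
        treated = [
            meta.index[(meta["pair_id"] == p) & (meta["condition"] == "treated")][0]
            for p in pairs
        ]
        control = [
            meta.index[(meta["pair_id"] == p) & (meta["condition"] == "control")][0]
            for p in pairs
        ]
        diff = self.abundances[treated].to_numpy() - self.abundances[control].to_numpy()
        return pd.DataFrame(diff, index=self.abundances.index, columns=pairs)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write features x samples with #condition/#pair header rows."""
    with open(path, "w") as fh:
        samples = list(matrix.abundances.columns)
        fh.write(
            "#condition\t\t"
            + "\t".join(matrix.samples.loc[s, "condition"] for s in samples)
            + "\n"
        )
        fh.write(
            "#pair\t\t"
            + "\t".join(str(matrix.samples.loc[s, "pair_id"]) for s in samples)
            + "\n"
        )
        fh.write("feature_id\tunique_peptides\t" + "\t".join(samples) + "\n")
        for feat in matrix.abundances.index:
            vals = "\t".join(f"{v:.6g}" for v in matrix.abundances.loc[feat])
            fh.write(f"{feat}\t{int(matrix.unique_peptides[feat])}\t{vals}\n")


def read_expression_tsv(path) -> ExpressionMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    meta: dict[str, list[str]] = {}
    while lines and lines[0].startswith("#"):
        key, _, *vals = lines.pop(0).split("\t")
        meta[key.lstrip("#")] = vals
    if "condition" not in meta or "pair" not in meta:
        raise FormatError(f"{path}: missing #condition/#pair header rows")
    header = lines[0].split("\t")
    if header[:2] != ["feature_id", "unique_peptides"]:
        raise FormatError(f"{path}: expected feature_id/unique_peptides columns")
    sample_ids = header[2:]
    feats, peps, rows = [], [], []
    for i, raw in enumerate(lines[1:], start=2):
        cells = raw.split("\t")
        if len(cells) != len(sample_ids) + 2:
            raise FormatError(f"{path}: data row {i}: ragged row")
        feats.append(cells[0])
        peps.append(int(cells[1]))
        rows.append([float(v) for v in cells[2:]])
    abundances = pd.DataFrame(rows, index=feats, columns=sample_ids)
    samples = pd.DataFrame(
        {"condition": meta["condition"], "pair_id": meta["pair"]}, index=sample_ids
    )
    peptides = pd.Series(peps, index=feats, name="unique_peptides")
    return ExpressionMatrix(abundances, samples, peptides)


def write_results_tsv(results: pd.DataFrame, path) -> None:
    """Write any results table as TSV (no index column)."""
    results.to_csv(path, sep="\t", index=False)
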