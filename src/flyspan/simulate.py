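"""Synthetic study generator with known ground truth.

Emulates the design of a diet-restriction lifespan GWAS in an inbred fly
panel: fully homozygous biallelic genotypes for L lines, per-fly death times
under ad-libitum (AL) and dietary-restriction (DR) feeding, paired proteomic
abundance matrices with planted fold-changes, and gene lists with a
controllable overlap. Every generator is deterministic given its seed, and
each component draws from an independent substream of the master seed so a
single dataset can be regenerated piecewise.

Lifespans follow a Gompertz mortality law with hazard ``a * exp(b * t)``
(the standard demographic model for adult flies), sampled by inverse CDF.
Lines carrying the alternate allele at the causal marker have their baseline
hazard multiplied by ``effect_dr`` under DR and ``effect_al`` under AL, so
``effect_al = 1 < effect_dr`` produces an allele that shortens lifespan
under DR but not AL. Death times are rounded UP to the next multiple of the
check interval: flies are found dead at the next scheduled transfer, two
days apart by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flyspan.errors import ConfigError
from flyspan.io import ALT, MISSING, REF, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

# Substream tags: SeedSequence([seed, tag]) per component.
_STREAM_GENOTYPES = 0
_STREAM_LIFESPANS = 1
_STREAM_OMICS = 2
_STREAM_GENE_LISTS = 3


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic panel.

    Defaults reproduce the study conditions the generator emulates: ~100-line
    panels genotyped at common variants (MAF in [0.25, 0.5], matching the
    post-filter regime of a >=25% MAF scan), 100 flies per line per diet,
    deaths recorded at 2-day transfers, and a Gompertz law (a = 1.2e-4/day,
    b = 0.15/day) whose median lifespan is ~45 days.
    """

    n_lines: int = 100
    n_markers: int = 500
    maf_range: tuple[float, float] = (0.25, 0.5)
    missing_rate: float = 0.02
    causal_marker_index: int | None = None
    effect_dr: float = 1.0  # hazard multiplier for the alt allele under DR
    effect_al: float = 1.0  # same under AL
    gompertz_baseline_a: float = 1.2e-4  # initial hazard per day
    gompertz_b: float = 0.15  # hazard growth rate per day
    flies_per_line: int = 100
    check_interval_days: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_lines < 0 or self.n_markers < 0:
            raise ConfigError("n_lines and n_markers must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.flies_per_line < 1:
            raise ConfigError("flies_per_line must be >= 1")
        if self.check_interval_days < 1:
            raise ConfigError("check_interval_days must be >= 1")
        if self.effect_dr < 0 or self.effect_al < 0:
            raise ConfigError("hazard effects must be >= 0")
        if self.gompertz_baseline_a <= 0 or self.gompertz_b <= 0:
            raise ConfigError("Gompertz parameters must be positive")
        if self.causal_marker_index is not None and not (
            0 <= self.causal_marker_index < self.n_markers
        ):
            raise ConfigError(
                f"causal_marker_index {self.causal_marker_index} out of range "
                f"for {self.n_markers} markers"
            )


@dataclass
class GroundTruth:
    """What the generator planted, so downstream calls can be scored."""

    causal_marker_id: str | None = None
    true_medians: pd.DataFrame | None = None  # line_id, diet, true_median (days)
    de_feature_ids: list[str] = field(default_factory=list)
    de_log2fc: float = 0.0
    overlap_gene_count: int | None = None


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _line_ids(n: int) -> list[str]:
    return [f"L{i + 1:04d}" for i in range(n)]


def _marker_ids(n: int) -> list[str]:
    return [f"M{i + 1:06d}" for i in range(n)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Homozygous biallelic calls at markers with MAF drawn from ``maf_range``.

    Each marker's alternate-line frequency is uniform on ``maf_range``; calls
    are independently set missing at ``missing_rate``. Markers get synthetic
    coordinates on contig "2L", 100 bp apart, so gene annotation is
    exercisable.
    """
    rng = _rng(config.seed, _STREAM_GENOTYPES)
    L, M = config.n_lines, config.n_markers
    freqs = rng.uniform(*config.maf_range, size=M)
    calls = np.where(rng.random((L, M)) < freqs, ALT, REF).astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random((L, M)) < config.missing_rate] = MISSING
    positions = (np.arange(M, dtype=np.int64) + 1) * 100
    return GenotypeMatrix(
        _line_ids(L),
        _marker_ids(M),
        calls,
        np.array(["2L"] * M, dtype=object),
        positions,
    )


def sample_gompertz(
    rng: np.random.Generator, a: float, b: float, size: int
) -> np.ndarray:
    """Inverse-CDF draws from Gompertz survival S(t) = exp(-(a/b)(e^{bt}-1))."""
    u = rng.random(size)
    return np.log1p(-(b / a) * np.log1p(-u)) / b


def gompertz_median(a: float, b: float) -> float:
    """Continuous median of the Gompertz law with hazard a*exp(b*t)."""
    return np.log1p(b * np.log(2.0) / a) / b


def simulate_lifespans(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-fly death records and per-line median lifespans for both diets.

    Returns ``(deaths, phenotypes, truth)``: a death table
    (group_id, diet, death_day, censored), the per-line medians of the
    recorded (discretized) death days, and the planted truth with analytic
    continuous medians. A line counts as an alt carrier if its call at the
    causal marker is ALT; missing calls count as non-carriers for lifespan
    generation.
    """
    if config.causal_marker_index is not None and config.causal_marker_index >= (
        genotypes.n_markers
    ):
        raise ConfigError(
            f"causal_marker_index {config.causal_marker_index} out of range "
            f"for {genotypes.n_markers} markers"
        )
    rng = _rng(config.seed, _STREAM_LIFESPANS)
    a, b = config.gompertz_baseline_a, config.gompertz_b
    ci = config.check_interval_days
    causal_id = None
    carrier = np.zeros(genotypes.n_lines, dtype=bool)
    if config.causal_marker_index is not None:
        causal_id = genotypes.marker_ids[config.causal_marker_index]
        carrier = genotypes.calls[:, config.causal_marker_index] == ALT

    death_rows: list[pd.DataFrame] = []
    pheno_rows: list[tuple[str, str, float]] = []
    truth_rows: list[tuple[str, str, float]] = []
    effects = {"AL": config.effect_al, "DR": config.effect_dr}
    for i, line_id in enumerate(genotypes.line_ids):
        for diet in ("AL", "DR"):
            mult = effects[diet] if carrier[i] else 1.0
            t = sample_gompertz(rng, a * mult, b, config.flies_per_line)
            days = np.maximum(np.ceil(t / ci), 1).astype(np.int64) * ci
            death_rows.append(
                pd.DataFrame(
                    {
                        "group_id": line_id,
                        "diet": diet,
                        "death_day": days,
                        "censored": False,
                    }
                )
            )
            pheno_rows.append((line_id, diet, float(np.median(days))))
            truth_rows.append((line_id, diet, gompertz_median(a * mult, b)))

    deaths = pd.concat(death_rows, ignore_index=True)
    phenotypes = pd.DataFrame(
        pheno_rows, columns=["line_id", "diet", "median_lifespan"]
    )
    truth = GroundTruth(
        causal_marker_id=causal_id,
        true_medians=pd.DataFrame(
            truth_rows, columns=["line_id", "diet", "true_median"]
        ),
    )
    return deaths, phenotypes, truth


def simulate_omics(
    n_features: int,
    n_pairs: int,
    n_de: int,
    log2fc_de: float = 1.0,
    sigma: float = 0.2,
    seed: int = 0,
    frac_single_peptide: float = 0.1,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Paired treated/control log2 abundance matrix with planted DE features.

    ``n_de`` randomly chosen features are shifted by ``log2fc_de`` in the
    treated condition; per-sample Gaussian noise has SD ``sigma``. A fraction
    of features carries a single unique peptide, to exercise the >=2-peptide
    evidence filter.
    """
    if n_de > n_features:
        raise ConfigError(f"n_de={n_de} exceeds n_features={n_features}")
    if n_pairs < 1 or n_features < 0:
        raise ConfigError("need n_pairs >= 1 and n_features >= 0")
    rng = _rng(seed, _STREAM_OMICS)
    feats = [f"P{i + 1:05d}" for i in range(n_features)]
    base = rng.normal(20.0, 2.0, size=n_features)
    de_idx = rng.choice(n_features, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    shift = np.zeros(n_features)
    shift[de_idx] = log2fc_de

    pairs = [f"R{j + 1}" for j in range(n_pairs)]
    cols, conds, pair_ids, data = [], [], [], []
    for j, pair in enumerate(pairs):
        control = base + rng.normal(0.0, sigma, size=n_features)
        treated = base + shift + rng.normal(0.0, sigma, size=n_features)
        cols += [f"ctl_{pair}", f"trt_{pair}"]
        conds += ["control", "treated"]
        pair_ids += [pair, pair]
        data += [control, treated]
    abundances = pd.DataFrame(
        np.column_stack(data) if data else np.empty((n_features, 0)),
        index=feats,
        columns=cols,
    )
    samples = pd.DataFrame({"condition": conds, "pair_id": pair_ids}, index=cols)
    single = rng.random(n_features) < frac_single_peptide
    peptides = pd.Series(
        np.where(single, 1, 2 + rng.poisson(3.0, size=n_features)),
        index=feats,
        name="unique_peptides",
    )
    truth = GroundTruth(
        de_feature_ids=[feats[i] for i in sorted(de_idx)], de_log2fc=log2fc_de
    )
    return ExpressionMatrix(abundances, samples, peptides), truth


def simulate_gene_lists(
    universe_size: int,
    size_a: int,
    size_b: int,
    overlap: int,
    seed: int = 0,
) -> tuple[set[str], set[str], list[str]]:
    """Two gene sets over a shared universe with exactly ``overlap`` shared ids."""
    if not (0 <= overlap <= min(size_a, size_b)):
        raise ConfigError(f"overlap {overlap} exceeds min(size_a, size_b)")
    if max(size_a, size_b) > universe_size:
        raise ConfigError("set sizes exceed universe size")
    if size_a + size_b - overlap > universe_size:
        raise ConfigError("universe too small for the requested disjoint parts")
    rng = _rng(seed, _STREAM_GENE_LISTS)
    universe = [f"G{i + 1:05d}" for i in range(universe_size)]
    order = rng.permutation(universe_size)
    shared = order[:overlap]
    only_a = order[overlap : size_a]
    only_b = order[size_a : size_a + size_b - overlap]
    set_a = {universe[i] for i in np.concatenate([shared, only_a]).astype(int)}
    set_b = {universe[i] for i in np.concatenate([shared, only_b]).astype(int)}
    return set_a, set_b, universe
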