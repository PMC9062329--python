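"""Quantification and coverage-response analysis.

TPM computation, binomial downsampling of count matrices with replicate
draws, per-gene accuracy (squared Pearson correlation against the
full-coverage data), expression filtering and stratification, and fitting
of the mean-R2-versus-coverage response curve used for study design.

Coverage throughout means mapped reads per sample, in millions. Count-level
binomial thinning is the count-space equivalent of uniform per-read
subsampling: if each read is kept independently with probability p, the
per-gene counts are exactly Binomial(c, p).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConsistencyError, FitError, ParameterError, StatisticError
from .sim import GenePanel, ReadCountMatrix, TPM_SCALE

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a unit flag ('tpm' or 'log2tpm')."""

    values: np.ndarray
    gene_id: np.ndarray
    sample_id: np.ndarray
    unit: str = "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.values.shape != (self.gene_id.size, self.sample_id.size):
            raise ConsistencyError("expression matrix shape does not match ids")
        if self.unit == "tpm" and np.any(self.values < 0):
            raise ParameterError("TPM values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.gene_id.size

    @property
    def n_samples(self) -> int:
        return self.sample_id.size

    def log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        if self.unit != "tpm":
            raise ParameterError("log2 transform expects TPM input")
        return ExpressionMatrix(
            np.log2(self.values + pseudocount), self.gene_id, self.sample_id, unit="log2tpm"
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_id)
        df.insert(0, "gene_id", self.gene_id)
        return df


@dataclasses.dataclass
class CoverageResponsePoint:
    """Accuracy of one downsampling replicate against the full data."""

    coverage: float
    replicate_id: int
    per_gene_r2: np.ndarray  # NaN where Pearson is undefined
    mean_r2: float
    n_excluded: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.mean_r2) or 0.0 <= self.mean_r2 <= 1.0 + 1e-12):
            raise ParameterError("mean R2 must lie in [0, 1]")


def counts_to_tpm(counts: ReadCountMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Transcripts per million: TPM_is = (c_is / L_i) / sum_j (c_js / L_j) * 1e6.

    All-zero sample columns map to all-zero TPM columns (logged).
    """
    if not np.array_equal(counts.gene_id, panel.gene_id):
        raise ConsistencyError("counts and panel gene sets differ")
    rate = counts.counts / panel.length[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("%d all-zero sample column(s) in counts_to_tpm", int(zero.sum()))
        colsum[zero] = 1.0
    return ExpressionMatrix(
        rate / colsum * TPM_SCALE, counts.gene_id.copy(), counts.sample_id.copy(), unit="tpm"
    )


def downsample_counts(
    counts: ReadCountMatrix,
    target_coverage: float,
    n_replicates: int = 5,
    seed: int = 0,
    allow_partial: bool = False,
) -> list[ReadCountMatrix]:
    """Binomial thinning of each sample to ``target_coverage`` million reads.

    Per sample the keep probability is p_s = target / current coverage and
    thinned counts are Binomial(c_is, p_s) independently per gene — the exact
    count-level law of keeping each read with probability p_s. Replicates
    differ only by sub-seed; requesting more coverage than a sample has is an
    error (no upsampling) unless ``allow_partial`` is set, in which case such
    samples keep all their reads (p_s clamped to 1, logged).
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if target_coverage < 0:
        raise ParameterError("target coverage must be non-negative")
    current = counts.library_size
    shallow = target_coverage > current * (1 + 1e-12)
    if shallow.any():
        if not allow_partial:
            raise ParameterError(
                f"target coverage {target_coverage}M exceeds a sample's current coverage "
                f"(min {current.min():.3f}M); downsampling cannot upsample"
            )
        logger.info(
            "%d sample(s) below target %.3fM keep all reads", int(shallow.sum()), target_coverage
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(current > 0, np.minimum(target_coverage / current, 1.0), 0.0)
    out = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([int(seed), rep])
        thinned = rng.binomial(counts.counts, p[None, :])
        out.append(
            ReadCountMatrix(thinned, counts.gene_id.copy(), counts.sample_id.copy())
        )
    return out


def per_gene_r2(
    full: ExpressionMatrix,
    reduced: ExpressionMatrix,
    coverage: float = float("nan"),
    replicate_id: int = 0,
) -> CoverageResponsePoint:
    """Squared Pearson correlation per gene, across samples, full vs reduced.

    Genes with zero variance in either matrix are excluded from the mean and
    counted in ``n_excluded`` (Pearson is undefined there; imputing 0 would
    conflate 'undetected' with 'uncorrelated').
    """
    if not np.array_equal(full.gene_id, reduced.gene_id) or not np.array_equal(
        full.sample_id, reduced.sample_id
    ):
        raise ConsistencyError("full and reduced matrices must share genes and samples")
    if full.n_samples < 3:
        raise StatisticError("per-gene correlation needs at least 3 samples")
    xf = full.values - full.values.mean(axis=1, keepdims=True)
    xr = reduced.values - reduced.values.mean(axis=1, keepdims=True)
    nf = np.sqrt((xf**2).sum(axis=1))
    nr = np.sqrt((xr**2).sum(axis=1))
    defined = (nf > 0) & (nr > 0)
    r2 = np.full(full.n_genes, np.nan)
    r = (xf[defined] * xr[defined]).sum(axis=1) / (nf[defined] * nr[defined])
    r2[defined] = np.clip(r, -1.0, 1.0) ** 2
    n_excluded = int((~defined).sum())
    mean = float(np.nanmean(r2)) if defined.any() else float("nan")
    return CoverageResponsePoint(
        coverage=coverage,
        replicate_id=replicate_id,
        per_gene_r2=r2,
        mean_r2=mean,
        n_excluded=n_excluded,
    )


def expression_filter(
    tpm: ExpressionMatrix, threshold: float = 0.1, fraction: float = 0.20
) -> np.ndarray:
    """Boolean gene mask: TPM strictly above ``threshold`` in at least
    ceil(fraction * n_samples) samples."""
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must lie in [0, 1]")
    if tpm.unit != "tpm":
        raise ParameterError("expression_filter expects TPM input")
    need = int(np.ceil(fraction * tpm.n_samples))
    return (tpm.values > threshold).sum(axis=1) >= need


def stratify_by_expression(tpm: ExpressionMatrix, n_strata: int = 5) -> np.ndarray:
    """Ascending expression strata (0 = lowest mean TPM), sizes differing by <= 1.

    Genes are ranked by mean TPM across samples; ties break by gene order
    (stable sort), mirroring the quintile stratification used to study how
    quantification accuracy depends on relative abundance.
    """
    if n_strata < 2:
        raise ParameterError("n_strata must be >= 2")
    m = tpm.n_genes
    if m < n_strata:
        raise ParameterError("fewer genes than strata")
    order = np.argsort(tpm.values.mean(axis=1), kind="stable")
    sizes = np.full(n_strata, m // n_strata)
    sizes[: m % n_strata] += 1
    labels = np.empty(m, dtype=np.int64)
    labels[order] = np.repeat(np.arange(n_strata), sizes)
    return labels


@dataclasses.dataclass
class CoverageResponseCurve:
    """Fitted mean-R2 response to coverage, with mapping-rate adjustment.

    The default model is mean R2 = alpha + beta_ln * ln(x) with x the
    expected (mapped) coverage in million reads/sample, clamped to [0, 1]
    on evaluation. ``evaluate(target)`` first converts target to expected
    coverage via the stored mapping rate; ``predict(x)`` takes expected
    coverage directly. A saturating alternative rmax * x / (x + kappa) is
    available via model="saturating".
    """

    alpha: float
    beta_ln: float
    mapping_rate: float = 1.0
    model: str = "log"
    rmax: float = float("nan")
    kappa: float = float("nan")
    fit_points: pd.DataFrame | None = None
    residuals: np.ndarray | None = None

    def predict(self, expected_coverage) -> np.ndarray:
        x = np.asarray(expected_coverage, dtype=float)
        if np.any(x <= 0):
            raise ParameterError("coverage must be positive")
        if self.model == "log":
            y = self.alpha + self.beta_ln * np.log(x)
        elif self.model == "saturating":
            y = self.rmax * x / (x + self.kappa)
        else:
            raise ParameterError(f"unknown curve model: {self.model}")
        return np.clip(y, 0.0, 1.0)

    def evaluate(self, target_coverage) -> np.ndarray:
        """Curve value at a *target* coverage, i.e. predict(target * mapping_rate)."""
        return self.predict(np.asarray(target_coverage, dtype=float) * self.mapping_rate)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "alpha": float(self.alpha),
            "beta_ln": float(self.beta_ln),
            "mapping_rate": float(self.mapping_rate),
            "rmax": float(self.rmax),
            "kappa": float(self.kappa),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoverageResponseCurve":
        return cls(
            alpha=float(d["alpha"]),
            beta_ln=float(d["beta_ln"]),
            mapping_rate=float(d.get("mapping_rate", 1.0)),
            model=d.get("model", "log"),
            rmax=float(d.get("rmax", float("nan"))),
            kappa=float(d.get("kappa", float("nan"))),
        )


def fit_coverage_response(
    points: Sequence[CoverageResponsePoint],
    mapping_rate: float = 1.0,
    model: str = "log",
) -> CoverageResponseCurve:
    """Least-squares fit of mean R2 against coverage.

    The points are measured at mapped coverages; the returned curve applies
    ``mapping_rate`` at evaluation time so that the value at a *target*
    coverage b equals the raw curve at the expected coverage b * mapping_rate.
    """
    if not 0.0 < mapping_rate <= 1.0:
        raise ParameterError("mapping rate must lie in (0, 1]")
    cov = np.array([p.coverage for p in points], dtype=float)
    y = np.array([p.mean_r2 for p in points], dtype=float)
    if np.unique(cov).size < 2:
        raise FitError("need at least two distinct coverages to fit a curve")
    if np.any((y < 0) | (y > 1)):
        raise ParameterError("mean R2 values must lie in [0, 1]")
    summary = pd.DataFrame(
        {
            "coverage": cov,
            "replicate_id": [p.replicate_id for p in points],
            "mean_r2": y,
            "n_excluded": [p.n_excluded for p in points],
        }
    )
    if model == "log":
        beta_ln, alpha = np.polyfit(np.log(cov), y, 1)
        if beta_ln < 0:
            warnings.warn(
                "fitted coverage response is decreasing in coverage; "
                "a non-monotone response is suspect",
                stacklevel=2,
            )
        resid = y - (alpha + beta_ln * np.log(cov))
        return CoverageResponseCurve(
            alpha=float(alpha),
            beta_ln=float(beta_ln),
            mapping_rate=mapping_rate,
            model="log",
            fit_points=summary,
            residuals=resid,
        )
    if model == "saturating":
        (rmax, kappa), _ = curve_fit(
            lambda x, rmax, kappa: rmax * x / (x + kappa),
            cov,
            y,
            p0=(min(1.0, float(y.max())), float(np.median(cov))),
            bounds=([0.0, 1e-9], [1.0, np.inf]),
            maxfev=10_000,
        )
        resid = y - rmax * cov / (cov + kappa)
        return CoverageResponseCurve(
            alpha=float("nan"),
            beta_ln=float("nan"),
            mapping_rate=mapping_rate,
            model="saturating",
            rmax=float(rmax),
            kappa=float(kappa),
            fit_points=summary,
            residuals=resid,
        )
    raise ParameterError(f"unknown curve model: {model}")


def coverage_response_table(
    counts: ReadCountMatrix,
    panel: GenePanel,
    coverage_grid: Sequence[float],
    n_replicates: int = 5,
    seed: int = 0,
) -> tuple[list[CoverageResponsePoint], pd.DataFrame]:
    """Downsample to each coverage in the grid and score accuracy vs the full data.

    Returns all replicate points plus a tidy table (coverage, replicate,
    mean_r2, n_excluded). Sub-seeds: [seed, grid index, replicate].
    """
    tpm_full = counts_to_tpm(counts, panel)
    points: list[CoverageResponsePoint] = []
    for ci, cov in enumerate(coverage_grid):
        reps = downsample_counts(
            counts, cov, n_replicates=n_replicates, seed=_grid_seed(seed, ci), allow_partial=True
        )
        for rep_id, thinned in enumerate(reps):
            tpm_red = counts_to_tpm(thinned, panel)
            points.append(per_gene_r2(tpm_full, tpm_red, coverage=cov, replicate_id=rep_id))
    table = pd.DataFrame(
        {
            "coverage": [p.coverage for p in points],
            "replicate": [p.replicate_id for p in points],
            "mean_r2": [p.mean_r2 for p in points],
            "n_excluded": [p.n_excluded for p in points],
        }
    )
    return points, table


def _grid_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(1000 + index,))
    return int(ss.generate_state(1)[0] % (2**31))
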