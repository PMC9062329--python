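"""Cis-eQTL mapping with permutation-based gene-level significance.

The scan follows the standard single-SNP design: for each sufficiently
expressed gene, every SNP within +/- 1 Mb of the TSS is tested by simple
OLS of the covariate-residualized phenotype on dosage; gene-level
significance comes from a permutation pass whose statistic is the maximum
absolute genotype-phenotype correlation across the window; eGenes are
called by FDR correction (Storey q-value by default, Benjamini-Hochberg
optional) of the gene-level p-values.

Coordinates are 1-based inclusive; cis windows are clipped at position 1.
Monomorphic SNPs and SNPs with empirical MAF below a threshold are dropped
before testing.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, ParameterError, StatisticError
from .quantify import ExpressionMatrix, counts_to_tpm, expression_filter
from .sim import CIS_WINDOW_BP, GenePanel, GenotypePanel, ReadCountMatrix

logger = logging.getLogger(__name__)

_MIN_P = float(np.nextafter(0, 1))


class CisWindow(NamedTuple):
    """1-based inclusive cis window around a TSS, floored at position 1."""

    gene_id: str
    chrom: str
    start: int
    end: int


def cis_window(gene_id: str, chrom: str, tss: int, window_bp: int = CIS_WINDOW_BP) -> CisWindow:
    return CisWindow(gene_id, chrom, max(1, int(tss) - window_bp), int(tss) + window_bp)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _principal_components(x: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top PCs (scores) of samples x features matrix, deterministic signs.

    Columns are centered; each component is oriented so its largest-magnitude
    feature loading is positive.
    """
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    for k in range(min(n_pcs, vt.shape[0])):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            pcs[:, k] = -pcs[:, k]
    return pcs


def compute_covariates(
    genotypes: GenotypePanel,
    expression: ExpressionMatrix,
    n_geno_pcs: int = 3,
    n_expr_pcs: int = 10,
) -> np.ndarray:
    """Covariate matrix: intercept, genotype PCs, expression PCs.

    Expression PCs are computed on log2(TPM + 1) when the input is TPM.
    Requesting at least n_samples PCs (plus the intercept's df) is an error.
    """
    n = genotypes.n_samples
    if expression.n_samples != n:
        raise ConsistencyError("genotypes and expression sample counts differ")
    if n_geno_pcs < 0 or n_expr_pcs < 0:
        raise ParameterError("PC counts must be non-negative")
    if n_geno_pcs + n_expr_pcs + 2 > n:
        raise ParameterError("requested more PCs than samples support")
    cols = [np.ones(n)]
    if n_geno_pcs > 0:
        cols.append(_principal_components(genotypes.dosages.astype(float), n_geno_pcs))
    if n_expr_pcs > 0:
        expr = expression.log2() if expression.unit == "tpm" else expression
        cols.append(_principal_components(expr.values.T, n_expr_pcs))
    return np.column_stack(cols)


def residualize(y: np.ndarray, covariates: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """OLS residuals of y on the covariates, collinear columns dropped.

    Residuals are orthogonal to every retained covariate column.
    """
    y = np.asarray(y, dtype=float)
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != y.size:
        raise ConsistencyError("covariate rows must match phenotype length")
    q, r, piv = scipy.linalg.qr(c, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * diag[0]).sum()) if diag.size and diag[0] > 0 else 0
    if rank == 0:
        raise StatisticError("covariate matrix has rank 0")
    qk = q[:, :rank]
    return y - qk @ (qk.T @ y)


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def nominal_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    snp_id: np.ndarray,
    snp_pos: np.ndarray,
    tss: int,
    gene_id: str = "",
) -> pd.DataFrame:
    """Per-SNP simple OLS of phenotype on dosage with two-sided t p-values.

    Monomorphic SNPs are dropped (logged). Records are sorted by nominal p.
    A perfect fit (zero residual) gets the minimum representable p and is
    flagged in ``perfect_fit``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise StatisticError("nominal scan needs at least 3 samples")
    g = np.asarray(dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    poly = g.std(axis=0) > 0
    if not poly.any():
        logger.warning("gene %s: all window SNPs monomorphic", gene_id)
        return _empty_records()
    if (~poly).any():
        logger.info("gene %s: dropped %d monomorphic SNP(s)", gene_id, int((~poly).sum()))
    g = g[:, poly]
    snp_id = np.asarray(snp_id, dtype=object)[poly]
    snp_pos = np.asarray(snp_pos, dtype=np.int64)[poly]
    gc = g - g.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxy = (gc * yc[:, None]).sum(axis=0)
    beta = sxy / sxx
    df = n - 2
    sse = np.maximum((yc**2).sum() - beta**2 * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx)
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    perfect = se == 0
    p = np.where(perfect, _MIN_P, np.maximum(p, _MIN_P))
    if perfect.any():
        logger.warning("gene %s: %d perfect-fit SNP(s), p floored", gene_id, int(perfect.sum()))
    out = pd.DataFrame(
        {
            "gene_id": gene_id,
            "snp_id": snp_id,
            "beta": beta,
            "se": se,
            "nominal_p": p,
            "distance_to_tss": snp_pos - int(tss),
            "perfect_fit": perfect,
        }
    )
    return out.sort_values("nominal_p", kind="stable").reset_index(drop=True)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene_id", "snp_id", "beta", "se", "nominal_p", "distance_to_tss", "perfect_fit"]
    )


def select_leading_snp(records: pd.DataFrame) -> pd.Series:
    """Leading SNP: minimum nominal p; ties by smaller |distance|, then snp id."""
    if len(records) == 0:
        raise ParameterError("no association records to select from")
    r = records.assign(_absd=records["distance_to_tss"].abs())
    r = r.sort_values(["nominal_p", "_absd", "snp_id"], kind="stable")
    return records.loc[r.index[0]]


def _standardize_columns(g: np.ndarray) -> np.ndarray:
    gc = g - g.mean(axis=0, keepdims=True)
    norm = np.sqrt((gc**2).sum(axis=0))
    return gc / norm


class PermutationResult(NamedTuple):
    perm_p: float
    observed_stat: float
    beta_approx_p: float | None


def permutation_pass(
    y: np.ndarray,
    dosages: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    beta_approx: bool = False,
) -> PermutationResult | None:
    """Gene-level empirical p-value by phenotype permutation.

    The statistic is the maximum absolute Pearson correlation between the
    phenotype and any window SNP. perm_p = (1 + #{perm >= observed}) /
    (n_perm + 1). Optionally a Beta(a, b) distribution is fitted by MLE to
    the per-permutation minimum nominal p-values and the observed minimum
    p-value's Beta CDF is returned as an approximate gene-level p.

    Returns None (logged) when no polymorphic SNP is in the window.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    poly = g.std(axis=0) > 0
    if not poly.any():
        logger.warning("permutation pass skipped: no polymorphic SNP in window")
        return None
    g = g[:, poly]
    n = y.size
    if y.std() == 0:
        raise StatisticError("phenotype has zero variance")
    zg = _standardize_columns(g)
    zy = _standardize_columns(y[:, None])[:, 0]
    obs_r = np.abs(zy @ zg)
    observed = float(obs_r.max())
    rng = np.random.default_rng([int(seed)])
    perm = np.empty((n_perm, n))
    for i in range(n_perm):
        perm[i] = zy[rng.permutation(n)]
    perm_r = np.abs(perm @ zg)
    perm_stat = perm_r.max(axis=1)
    perm_p = (1.0 + float((perm_stat >= observed - 1e-12).sum())) / (n_perm + 1.0)
    beta_p = None
    if beta_approx:
        df = n - 2
        def min_p(r: np.ndarray) -> np.ndarray:
            r = np.clip(r, 0.0, 1.0 - 1e-12)
            t = r * np.sqrt(df / (1.0 - r**2))
            return np.maximum(2.0 * scipy.stats.t.sf(t, df), _MIN_P)
        pmins = min_p(perm_stat)
        a, b, _, _ = scipy.stats.beta.fit(np.clip(pmins, 1e-12, 1 - 1e-12), floc=0, fscale=1)
        beta_p = float(scipy.stats.beta.cdf(min_p(np.array([observed]))[0], a, b))
    return PermutationResult(perm_p=perm_p, observed_stat=observed, beta_approx_p=beta_p)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def storey_pi0(p: np.ndarray, lambda_: float = 0.5, smoother: bool = False) -> float:
    """Storey estimate of the null proportion pi0.

    Fixed-lambda: #{p > lambda} / (m (1 - lambda)). The smoother option
    evaluates pi0(lambda) on a grid and extrapolates a cubic polynomial fit
    at the largest lambda.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return 1.0
    if smoother:
        grid = np.arange(0.05, 0.96, 0.05)
        pi0s = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
        coef = np.polyfit(grid, pi0s, 3)
        pi0 = float(np.polyval(coef, grid[-1]))
    else:
        if not 0.0 < lambda_ < 1.0:
            raise ParameterError("lambda must lie in (0, 1)")
        pi0 = float((p > lambda_).sum() / (m * (1 - lambda_)))
    return float(min(max(pi0, 1.0 / m), 1.0))


def fdr_correct(
    gene_p: np.ndarray,
    method: str = "qvalue",
    level: float = 0.05,
    lambda_: float = 0.5,
    smoother: bool = False,
    pi0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """q-values and eGene flags (q < level) for gene-level p-values.

    method="qvalue": Storey q-values, i.e. pi0 times the Benjamini-Hochberg
    adjusted p-values (with pi0 = 1 the two are identical). method="bh":
    plain Benjamini-Hochberg.
    """
    p = np.asarray(gene_p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        q = bh
    elif method == "qvalue":
        if pi0 is None:
            pi0 = storey_pi0(p, lambda_=lambda_, smoother=smoother)
        q = np.minimum(pi0 * bh, 1.0)
    else:
        raise ParameterError(f"unknown FDR method: {method}")
    return q, q < level


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EGeneTable:
    """Per-gene leading association, permutation p, q-value and eGene flag."""

    table: pd.DataFrame
    fdr_level: float
    n_skipped: int = 0

    @property
    def n_egenes(self) -> int:
        return int(self.table["is_egene"].sum())


def map_cis_eqtls(
    panel: GenePanel,
    genotypes: GenotypePanel,
    counts: ReadCountMatrix | None = None,
    tpm: ExpressionMatrix | None = None,
    window_bp: int = CIS_WINDOW_BP,
    n_geno_pcs: int = 3,
    n_expr_pcs: int = 10,
    maf_min: float = 0.01,
    tpm_threshold: float = 0.1,
    tpm_fraction: float = 0.20,
    n_perm: int = 1000,
    fdr_level: float = 0.05,
    fdr_method: str = "qvalue",
    beta_approx: bool = False,
    use_beta_approx_p: bool = False,
    seed: int = 0,
) -> EGeneTable:
    """Full cis-eQTL pass: filter, residualize, scan, permute, FDR-correct.

    The phenotype is log2(TPM + 1) residualized on the covariates (intercept
    + genotype PCs + expression PCs). Gene-level significance uses the direct
    permutation p by default; set ``use_beta_approx_p`` (with ``beta_approx``)
    to feed the Beta-approximated p-values to the FDR step instead.
    """
    if counts is None and tpm is None:
        raise ParameterError("provide counts or tpm")
    if tpm is None:
        tpm = counts_to_tpm(counts, panel)
    if not np.array_equal(tpm.sample_id, genotypes.sample_id):
        raise ConsistencyError("expression and genotype samples differ")
    keep = expression_filter(tpm, threshold=tpm_threshold, fraction=tpm_fraction)
    covariates = compute_covariates(
        genotypes, tpm, n_geno_pcs=n_geno_pcs, n_expr_pcs=n_expr_pcs
    )
    log2tpm = tpm.log2()
    emp_af = genotypes.dosages.mean(axis=0) / 2.0
    emp_maf = np.minimum(emp_af, 1.0 - emp_af)
    rows = []
    n_skipped = 0
    for i in np.flatnonzero(keep):
        gid = panel.gene_id[i]
        win = cis_window(gid, panel.chrom[i], int(panel.tss[i]), window_bp)
        idx = genotypes.window_indices(win.chrom, win.start, win.end)
        idx = idx[emp_maf[idx] >= maf_min]
        if idx.size == 0:
            logger.info("gene %s skipped: no SNP passes MAF/monomorphic filters", gid)
            n_skipped += 1
            continue
        y = residualize(log2tpm.values[i], covariates)
        if y.std() == 0:
            n_skipped += 1
            continue
        records = nominal_scan(
            y,
            genotypes.dosages[:, idx],
            genotypes.snp_id[idx],
            genotypes.snp_pos[idx],
            int(panel.tss[i]),
            gene_id=gid,
        )
        if len(records) == 0:
            n_skipped += 1
            continue
        lead = select_leading_snp(records)
        perm = permutation_pass(
            y,
            genotypes.dosages[:, idx],
            n_perm=n_perm,
            seed=_gene_seed(seed, int(i)),
            beta_approx=beta_approx,
        )
        if perm is None:
            n_skipped += 1
            continue
        rows.append(
            {
                "gene_id": gid,
                "n_snps": len(records),
                "snp_id": lead["snp_id"],
                "distance_to_tss": int(lead["distance_to_tss"]),
                "beta": float(lead["beta"]),
                "se": float(lead["se"]),
                "nominal_p": float(lead["nominal_p"]),
                "perm_p": perm.perm_p,
                "beta_approx_p": perm.beta_approx_p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_snps",
            "snp_id",
            "distance_to_tss",
            "beta",
            "se",
            "nominal_p",
            "perm_p",
            "beta_approx_p",
        ],
    )
    if len(table):
        p_for_fdr = (
            table["beta_approx_p"].to_numpy(dtype=float)
            if use_beta_approx_p and beta_approx
            else table["perm_p"].to_numpy(dtype=float)
        )
        q, flags = fdr_correct(p_for_fdr, method=fdr_method, level=fdr_level)
        table["q_value"] = q
        table["is_egene"] = flags
    else:
        table["q_value"] = np.array([])
        table["is_egene"] = np.array([], dtype=bool)
    return EGeneTable(table=table, fdr_level=fdr_level, n_skipped=n_skipped)


def _gene_seed(seed: int, gene_index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(2000 + gene_index,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# cross-dataset concordance
# ---------------------------------------------------------------------------

def concordance(
    a: EGeneTable,
    b: EGeneTable,
    genotypes: GenotypePanel,
) -> dict:
    """Concordance metrics between two eQTL runs on the same genotype panel.

    Returns shared eGene and shared leading-eSNP counts, squared Pearson
    correlation of effect sizes over genes with the same leading eSNP, the
    OLS slope of -log10 p (dataset b on dataset a) over shared eGenes, and
    the mean LD r2 between the two leading eSNPs per shared eGene. Effect
    correlation is sign-insensitive (squared), which is logged.
    """
    ta = a.table.set_index("gene_id")
    tb = b.table.set_index("gene_id")
    common = ta.index.intersection(tb.index)
    if len(common) == 0:
        raise ConsistencyError("no overlapping genes between the two tables")
    ea = ta.loc[common, "is_egene"].to_numpy(dtype=bool)
    eb = tb.loc[common, "is_egene"].to_numpy(dtype=bool)
    shared = common[ea & eb]
    out: dict = {
        "n_genes_common": int(len(common)),
        "shared_egenes": int(len(shared)),
        "shared_leading_esnp": 0,
        "effect_r2": float("nan"),
        "neglog_p_slope": float("nan"),
        "mean_leading_ld_r2": float("nan"),
    }
    if len(shared) == 0:
        logger.warning("no shared eGenes; concordance metrics undefined")
        return out
    sa = ta.loc[shared]
    sb = tb.loc[shared]
    same = sa["snp_id"].to_numpy() == sb["snp_id"].to_numpy()
    out["shared_leading_esnp"] = int(same.sum())
    if same.sum() >= 2:
        r = np.corrcoef(
            sa.loc[same, "beta"].to_numpy(dtype=float),
            sb.loc[same, "beta"].to_numpy(dtype=float),
        )[0, 1]
        out["effect_r2"] = float(r**2)
        logger.info("effect_r2 is sign-insensitive (squared correlation)")
    if len(shared) >= 2:
        xa = -np.log10(sa["nominal_p"].to_numpy(dtype=float))
        xb = -np.log10(sb["nominal_p"].to_numpy(dtype=float))
        slope = np.polyfit(xa, xb, 1)[0]
        out["neglog_p_slope"] = float(slope)
    ld = []
    for gid in shared:
        ga = genotypes.dosages[:, genotypes.index_of(ta.loc[gid, "snp_id"])].astype(float)
        gb = genotypes.dosages[:, genotypes.index_of(tb.loc[gid, "snp_id"])].astype(float)
        if ga.std() == 0 or gb.std() == 0:
            continue
        ld.append(float(np.corrcoef(ga, gb)[0, 1] ** 2))
    if ld:
        out["mean_leading_ld_r2"] = float(np.mean(ld))
    return out
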