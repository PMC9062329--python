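"""Measurement-error attenuation theory for eQTL association power.

If y is the true expression of a gene, y~ a noisy estimate of it (e.g. from
lower-coverage sequencing), and R = cor(y, y~), then for a SNP with dosage g
(all variables standardized):

* the fitted effect on the noisy phenotype attenuates to R * beta;
* the chi-square-scale association statistic x = N * cor^2(g, y) attenuates
  to R^2 * x;
* a study of N samples with noisy expression therefore has the power of a
  study of Neff = R^2 * N perfectly measured samples, and statistical power
  falls by the factor 1 / R^2.

The derivation models y~ = R*y + eps with zero-mean noise, which leaves the
covariance algebra exact but does not scale eps by sqrt(1 - R^2); the
relation is therefore exact in expectation for standardized inputs and
approximate otherwise. ``attenuation_experiment`` validates the law
end-to-end against the package's own read-level simulator.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .quantify import counts_to_tpm, downsample_counts, expression_filter, per_gene_r2
from .sim import _sub, simulate_cohort


def attenuated_effect(beta_hat: float, r: float) -> float:
    """Effect size observed on a noisy phenotype: R * beta_hat.

    R is the correlation between true and estimated expression, taken
    non-negative (for anti-correlated estimates use the magnitude).
    """
    if not 0.0 <= r <= 1.0:
        raise ParameterError("R must lie in [0, 1]")
    return r * beta_hat


def attenuated_statistic(x_ground: float, r2: float) -> float:
    """Chi-square-scale association statistic under noisy expression: R^2 * x."""
    if x_ground < 0:
        raise ParameterError("association statistic must be non-negative")
    if not 0.0 <= r2 <= 1.0:
        raise ParameterError("R2 must lie in [0, 1]")
    return r2 * x_ground


def effective_n(n: float, r2_adj: float) -> float:
    """Effective sample size Neff = R2_adj * N (rounding left to callers)."""
    if n < 0:
        raise ParameterError("N must be non-negative")
    if not 0.0 <= r2_adj <= 1.0:
        raise ParameterError("R2_adj must lie in [0, 1]")
    return r2_adj * n


def power_fold_change(r2: float) -> float:
    """Fold reduction in statistical power at expression accuracy R2: 1 / R2."""
    if not 0.0 < r2 <= 1.0:
        raise ParameterError("R2 must lie in (0, 1]")
    return 1.0 / r2


def attenuation_table(r2_values) -> "np.ndarray":
    """Rows of (R2, effect attenuation R, statistic attenuation R2, power fold loss)."""
    r2 = np.asarray(r2_values, dtype=float)
    return np.column_stack([r2, np.sqrt(r2), r2, 1.0 / r2])


def attenuation_experiment(
    n_genes: int = 1000,
    n_samples: int = 300,
    thin_fraction: float = 0.1,
    reads_per_gene: float = 1089.0,
    snps_per_gene: int = 5,
    beta: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """End-to-end empirical check of the R2-attenuation law.

    Simulates a cohort at full coverage, thins the counts to
    ``thin_fraction`` of the reads, computes each gene's empirical R2
    between full and thinned TPM, and compares the chi-square association
    statistics N * cor^2(g, y) at the full-data leading SNP in the two
    datasets. Under the theory, the regression-through-origin slope of the
    low-coverage statistics on the full-coverage statistics equals the mean
    per-gene R2.

    ``reads_per_gene`` sets per-sample library size as reads_per_gene *
    n_genes; the default matches the per-gene depth of a 50 million
    read/sample experiment over a transcriptome-sized panel.

    Returns slope, mean R2, their difference, and per-gene arrays.
    """
    cohort = simulate_cohort(
        n_genes=n_genes,
        n_samples=n_samples,
        snps_per_gene=snps_per_gene,
        target_coverage_million=reads_per_gene * n_genes / 1e6,
        frac_egenes=1.0,
        beta=beta,
        noise_sd=noise_sd,
        seed=seed,
    )
    panel, genotypes = cohort.panel, cohort.genotypes
    tpm_full = counts_to_tpm(cohort.counts, panel)
    target = thin_fraction * reads_per_gene * n_genes / 1e6
    thinned = downsample_counts(
        cohort.counts, target, n_replicates=1, seed=_sub(seed, 6), allow_partial=True
    )[0]
    tpm_low = counts_to_tpm(thinned, panel)
    keep = expression_filter(tpm_full)
    point = per_gene_r2(tpm_full, tpm_low)
    r2_gene = point.per_gene_r2
    yf = np.log2(tpm_full.values + 1.0)
    yl = np.log2(tpm_low.values + 1.0)
    n = n_samples
    x_full, x_low, r2_used = [], [], []
    for i in range(n_genes):
        if not keep[i] or not np.isfinite(r2_gene[i]):
            continue
        if yf[i].std() == 0 or yl[i].std() == 0:
            continue
        start, end = panel.cis_window(i)
        idx = genotypes.window_indices(panel.chrom[i], start, end)
        g = genotypes.dosages[:, idx].astype(float)
        poly = g.std(axis=0) > 0
        if not poly.any():
            continue
        g = g[:, poly]
        rf = _cor_with(g, yf[i])
        lead = int(np.argmax(np.abs(rf)))
        rl = _cor_with(g[:, [lead]], yl[i])[0]
        x_full.append(n * rf[lead] ** 2)
        x_low.append(n * rl**2)
        r2_used.append(r2_gene[i])
    x_full = np.asarray(x_full)
    x_low = np.asarray(x_low)
    r2_used = np.asarray(r2_used)
    slope = float((x_full * x_low).sum() / (x_full**2).sum())
    mean_r2 = float(r2_used.mean())
    return {
        "slope": slope,
        "mean_r2": mean_r2,
        "difference": slope - mean_r2,
        "n_genes_used": int(x_full.size),
        "x_full": x_full,
        "x_low": x_low,
        "per_gene_r2": r2_used,
    }


def _cor_with(g: np.ndarray, y: np.ndarray) -> np.ndarray:
    gc = g - g.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((gc**2).sum(axis=0) * (yc**2).sum())
    return (gc * yc[:, None]).sum(axis=0) / denom
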