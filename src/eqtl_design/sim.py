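"""Synthetic cohort generator for eQTL study-design experiments.

Builds fully seeded, self-contained datasets that mimic the statistical
structure of a bulk RNA-seq eQTL cohort:

* a gene panel with heavy-tailed (log-normal) relative abundances, so that
  most genes are lowly expressed and a small top stratum carries most of the
  read mass;
* SNP dosages in Hardy-Weinberg proportions placed inside each gene's
  +/- 1 Mb cis window, with one designated causal variant per eGene plus
  null variants to exercise leading-SNP selection;
* per-gene cis effects acting additively on log2 abundance, with the
  genotype mean-centered so library composition stays comparable across
  dosage groups;
* read counts drawn per sample as a multinomial over length-weighted molar
  abundance, at library sizes that vary log-normally around a target
  (emulating the 1-50 million mapped reads/sample range of real cohorts).

All randomness flows from a single integer seed. Sub-streams are derived as
``numpy.random.default_rng([seed, *stream_indices])``; every public
operation is bit-reproducible given its seed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError

logger = logging.getLogger(__name__)

#: Half-width of a gene's cis window around the TSS, in bp.
CIS_WINDOW_BP = 1_000_000

#: TPM columns sum to this constant.
TPM_SCALE = 1.0e6

# Genes are spaced so adjacent cis windows never overlap and every SNP falls
# in exactly one gene's window.
_GENE_SPACING_BP = 2_500_000


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Generator for (seed, *stream) — the package-wide seed-splitting scheme."""
    if stream:
        return np.random.default_rng([int(seed), *(int(s) for s in stream)])
    return np.random.default_rng(int(seed))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenePanel:
    """Gene annotation plus ground-truth relative abundance.

    ``base_abundance`` is the expected molar abundance of each gene on TPM
    scale (non-negative; normalizable to 1e6 over the panel).
    Coordinates are 1-based.
    """

    gene_id: np.ndarray
    chrom: np.ndarray
    tss: np.ndarray
    length: np.ndarray
    biotype: np.ndarray
    base_abundance: np.ndarray

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.tss = np.asarray(self.tss, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        self.biotype = np.asarray(self.biotype, dtype=object)
        self.base_abundance = np.asarray(self.base_abundance, dtype=float)
        if len(set(self.gene_id)) != self.n_genes:
            raise ConsistencyError("gene ids must be unique")
        if np.any(self.length <= 0):
            raise ParameterError("gene lengths must be positive")
        if np.any(self.base_abundance < 0):
            raise ParameterError("base abundances must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.gene_id.size

    def cis_window(self, i: int) -> tuple[int, int]:
        """1-based inclusive cis window of gene ``i``, floored at position 1."""
        tss = int(self.tss[i])
        return max(1, tss - CIS_WINDOW_BP), tss + CIS_WINDOW_BP

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "chrom": self.chrom,
                "tss": self.tss,
                "length": self.length,
                "biotype": self.biotype,
                "base_abundance": self.base_abundance,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenePanel":
        return cls(
            gene_id=df["gene_id"].to_numpy(dtype=object),
            chrom=df["chrom"].astype(str).to_numpy(dtype=object),
            tss=df["tss"].to_numpy(),
            length=df["length"].to_numpy(),
            biotype=df["biotype"].to_numpy(dtype=object),
            base_abundance=df["base_abundance"].to_numpy(dtype=float),
        )


@dataclasses.dataclass
class GenotypePanel:
    """SNP dosages (samples x SNPs, values in {0,1,2}) with positions and MAF."""

    dosages: np.ndarray
    snp_id: np.ndarray
    chrom: np.ndarray
    snp_pos: np.ndarray
    maf: np.ndarray
    sample_id: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.snp_pos = np.asarray(self.snp_pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ParameterError("dosage entries must be in {0, 1, 2}")
        if len(set(self.snp_id)) != self.n_snps:
            raise ConsistencyError("snp ids must be unique")
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            raise ParameterError("maf must lie in (0, 0.5]")
        if self.dosages.shape != (self.n_samples, self.n_snps):
            raise ConsistencyError("dosage matrix shape does not match ids")

    @property
    def n_samples(self) -> int:
        return self.sample_id.size

    @property
    def n_snps(self) -> int:
        return self.snp_id.size

    def window_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of SNPs on ``chrom`` with 1-based position in [start, end]."""
        return np.flatnonzero(
            (self.chrom == chrom) & (self.snp_pos >= start) & (self.snp_pos <= end)
        )

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_id == snp_id)
        if hits.size == 0:
            raise ConsistencyError(f"unknown snp id: {snp_id}")
        return int(hits[0])


@dataclasses.dataclass
class EqtlTruth:
    """Per-gene ground truth: causal SNP id (or None), effect size, noise SD.

    ``beta`` is the effect per dosage unit on log2 abundance; ``noise_sd``
    is the SD of the residual on the same scale.
    """

    gene_id: np.ndarray
    causal_snp_id: np.ndarray
    beta: np.ndarray
    noise_sd: np.ndarray

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.causal_snp_id = np.asarray(self.causal_snp_id, dtype=object)
        self.beta = np.asarray(self.beta, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if not np.isfinite(self.beta).all():
            raise ParameterError("effect sizes must be finite")
        if np.any(self.noise_sd < 0):
            raise ParameterError("noise SD must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "causal_snp_id": [s if s is not None else "" for s in self.causal_snp_id],
                "beta": self.beta,
                "noise_sd": self.noise_sd,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EqtlTruth":
        causal = df["causal_snp_id"].fillna("").to_numpy(dtype=object)
        causal = np.array([c if c != "" else None for c in causal], dtype=object)
        return cls(
            gene_id=df["gene_id"].to_numpy(dtype=object),
            causal_snp_id=causal,
            beta=df["beta"].to_numpy(dtype=float),
            noise_sd=df["noise_sd"].to_numpy(dtype=float),
        )


@dataclasses.dataclass
class ReadCountMatrix:
    """Integer read counts, genes x samples; column sums are library sizes."""

    counts: np.ndarray
    gene_id: np.ndarray
    sample_id: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.counts.shape != (self.gene_id.size, self.sample_id.size):
            raise ConsistencyError("count matrix shape does not match ids")

    @property
    def library_size(self) -> np.ndarray:
        """Per-sample total mapped reads, in millions."""
        return self.counts.sum(axis=0) / 1.0e6

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_id)
        df.insert(0, "gene_id", self.gene_id)
        return df


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_gene_panel(
    n_genes: int,
    frac_coding: float = 0.5,
    abundance_meanlog: float = 0.0,
    abundance_sdlog: float = 2.0,
    length_range: tuple[int, int] = (200, 10_000),
    seed: int = 0,
    chrom: str = "1",
) -> GenePanel:
    """Draw a gene panel with heavy-tailed abundances.

    Abundances are log-normal(``abundance_meanlog``, ``abundance_sdlog``) on
    natural-log scale; lengths are log-uniform in ``length_range``; TSS
    positions are spaced 2.5 Mb apart on one chromosome so cis windows are
    well defined and mutually disjoint. ``frac_coding`` of the genes (rounded)
    are labelled protein_coding, assigned at random.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if not 0.0 <= frac_coding <= 1.0:
        raise ParameterError("frac_coding must lie in [0, 1]")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ParameterError("length_range must satisfy 0 < lo <= hi")
    rng = _rng(seed)
    abundance = rng.lognormal(abundance_meanlog, abundance_sdlog, size=n_genes)
    length = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes)).round().astype(np.int64)
    length = np.clip(length, lo, hi)
    n_coding = int(round(frac_coding * n_genes))
    biotype = np.array(["non_coding"] * n_genes, dtype=object)
    coding_idx = rng.choice(n_genes, size=n_coding, replace=False)
    biotype[coding_idx] = "protein_coding"
    width = max(4, len(str(n_genes)))
    gene_id = np.array([f"g{i + 1:0{width}d}" for i in range(n_genes)], dtype=object)
    tss = CIS_WINDOW_BP + np.arange(n_genes, dtype=np.int64) * _GENE_SPACING_BP
    return GenePanel(
        gene_id=gene_id,
        chrom=np.array([chrom] * n_genes, dtype=object),
        tss=tss,
        length=length,
        biotype=biotype,
        base_abundance=abundance,
    )


def simulate_genotypes(
    n_samples: int,
    snps_per_gene: int,
    panel: GenePanel,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypePanel:
    """Draw Hardy-Weinberg dosages for SNPs placed in each gene's cis window.

    Per SNP a minor-allele frequency is drawn uniformly in ``maf_range`` and
    dosages are Binomial(2, maf) across samples. Positions are uniform within
    the gene's +/- 1 Mb window (floored at 1).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must be a subset of (0, 0.5]")
    if n_samples < 1 or snps_per_gene < 1:
        raise ParameterError("n_samples and snps_per_gene must be >= 1")
    rng = _rng(seed)
    n_snps = panel.n_genes * snps_per_gene
    snp_id = np.empty(n_snps, dtype=object)
    chrom = np.empty(n_snps, dtype=object)
    snp_pos = np.empty(n_snps, dtype=np.int64)
    maf = rng.uniform(lo, hi, size=n_snps) if lo < hi else np.full(n_snps, lo)
    dosages = np.empty((n_samples, n_snps), dtype=np.int8)
    for i in range(panel.n_genes):
        start, end = panel.cis_window(i)
        sl = slice(i * snps_per_gene, (i + 1) * snps_per_gene)
        pos = np.sort(rng.integers(start, end + 1, size=snps_per_gene))
        snp_pos[sl] = pos
        chrom[sl] = panel.chrom[i]
        for j in range(snps_per_gene):
            snp_id[i * snps_per_gene + j] = f"{panel.gene_id[i]}_snp{j + 1}"
        dosages[:, sl] = rng.binomial(2, maf[sl], size=(n_samples, snps_per_gene))
    width = max(4, len(str(n_samples)))
    sample_id = np.array([f"s{i + 1:0{width}d}" for i in range(n_samples)], dtype=object)
    return GenotypePanel(
        dosages=dosages,
        snp_id=snp_id,
        chrom=chrom,
        snp_pos=snp_pos,
        maf=maf,
        sample_id=sample_id,
    )


def simulate_truth(
    panel: GenePanel,
    genotypes: GenotypePanel,
    frac_egenes: float = 1.0,
    beta: float = 0.5,
    beta_sd: float = 0.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> EqtlTruth:
    """Designate one causal cis SNP for a fraction of genes.

    Causal genes are a random subset of size round(frac_egenes * n_genes);
    each gets a causal SNP drawn uniformly from its cis window and an effect
    ``beta + beta_sd * Normal(0,1)`` on log2 abundance. Non-eGenes have no
    causal SNP and beta 0. ``noise_sd`` applies to every gene.
    """
    if not 0.0 <= frac_egenes <= 1.0:
        raise ParameterError("frac_egenes must lie in [0, 1]")
    rng = _rng(seed)
    n = panel.n_genes
    causal = np.array([None] * n, dtype=object)
    betas = np.zeros(n)
    n_egenes = int(round(frac_egenes * n))
    egene_idx = rng.choice(n, size=n_egenes, replace=False)
    for i in egene_idx:
        start, end = panel.cis_window(int(i))
        window = genotypes.window_indices(panel.chrom[i], start, end)
        if window.size == 0:
            raise ConsistencyError(f"gene {panel.gene_id[i]} has no cis SNPs")
        causal[i] = genotypes.snp_id[rng.choice(window)]
        betas[i] = beta + beta_sd * rng.standard_normal()
    return EqtlTruth(
        gene_id=panel.gene_id.copy(),
        causal_snp_id=causal,
        beta=betas,
        noise_sd=np.full(n, float(noise_sd)),
    )


def simulate_expression(
    panel: GenePanel,
    genotypes: GenotypePanel,
    truth: EqtlTruth,
    seed: int = 0,
) -> np.ndarray:
    """True per-sample abundance matrix (genes x samples, TPM scale).

    log2 theta_is = log2 theta_i + beta_i * (g_is - mean_s g_is) + eps_is,
    eps ~ Normal(0, noise_sd_i^2); columns are renormalized to sum to 1e6.
    Genes with zero base abundance stay exactly zero.
    """
    if not np.array_equal(panel.gene_id, truth.gene_id):
        raise ConsistencyError("panel and truth gene sets differ")
    rng = _rng(seed)
    n_genes, n_samples = panel.n_genes, genotypes.n_samples
    log2theta = np.full((n_genes, n_samples), -np.inf)
    expressed = panel.base_abundance > 0
    log2theta[expressed] = np.log2(panel.base_abundance[expressed])[:, None]
    for i in np.flatnonzero(expressed):
        snp = truth.causal_snp_id[i]
        if snp is not None and truth.beta[i] != 0.0:
            g = genotypes.dosages[:, genotypes.index_of(snp)].astype(float)
            log2theta[i] += truth.beta[i] * (g - g.mean())
        if truth.noise_sd[i] > 0:
            log2theta[i] += rng.normal(0.0, truth.noise_sd[i], size=n_samples)
    theta = np.where(np.isfinite(log2theta), np.exp2(log2theta), 0.0)
    colsum = theta.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        logger.warning("%d sample(s) have zero total abundance", int(zero_cols.sum()))
        colsum[zero_cols] = 1.0
    return theta / colsum * TPM_SCALE


def simulate_library_sizes(
    n_samples: int,
    target_million: float,
    sd_million: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample read totals, log-normal around a target (reads, not millions).

    Default SD is target/3, emulating the sample-to-sample spread of mapped
    reads seen in real cohorts.
    """
    if target_million <= 0:
        raise ParameterError("target coverage must be positive")
    if sd_million is None:
        sd_million = target_million / 3.0
    rng = _rng(seed)
    if sd_million == 0:
        return np.full(n_samples, int(round(target_million * 1e6)), dtype=np.int64)
    cv2 = (sd_million / target_million) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(target_million * 1e6) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n_samples).round().astype(np.int64)


def simulate_reads(
    abundance: np.ndarray,
    panel: GenePanel,
    library_sizes: Sequence[int],
    seed: int = 0,
    sample_id: np.ndarray | None = None,
) -> ReadCountMatrix:
    """Draw read counts per sample as Multinomial(T_s, pi) with pi ~ theta * length.

    The length weighting converts molar abundance (TPM scale) into read mass;
    column sums equal the requested library sizes exactly.
    """
    library_sizes = np.asarray(library_sizes, dtype=np.int64)
    if np.any(library_sizes < 0):
        raise ParameterError("library sizes must be non-negative")
    abundance = np.asarray(abundance, dtype=float)
    if abundance.shape[0] != panel.n_genes:
        raise ConsistencyError("abundance rows do not match the gene panel")
    n_samples = abundance.shape[1]
    if library_sizes.size != n_samples:
        raise ConsistencyError("one library size per sample required")
    rng = _rng(seed)
    mass = abundance * panel.length[:, None]
    counts = np.zeros((panel.n_genes, n_samples), dtype=np.int64)
    for s in range(n_samples):
        total = mass[:, s].sum()
        if total == 0:
            if library_sizes[s] > 0:
                raise ConsistencyError(f"sample {s} has zero read mass but reads requested")
            continue
        counts[:, s] = rng.multinomial(library_sizes[s], mass[:, s] / total)
    if sample_id is None:
        width = max(4, len(str(n_samples)))
        sample_id = np.array([f"s{i + 1:0{width}d}" for i in range(n_samples)], dtype=object)
    return ReadCountMatrix(counts=counts, gene_id=panel.gene_id.copy(), sample_id=sample_id)


@dataclasses.dataclass
class SimulatedCohort:
    """Bundle of every ground-truth piece of one simulated cohort."""

    panel: GenePanel
    genotypes: GenotypePanel
    truth: EqtlTruth
    abundance: np.ndarray
    counts: ReadCountMatrix


def simulate_cohort(
    n_genes: int,
    n_samples: int,
    snps_per_gene: int = 8,
    target_coverage_million: float = 10.0,
    coverage_sd_million: float | None = None,
    frac_coding: float = 0.5,
    abundance_sdlog: float = 2.0,
    frac_egenes: float = 1.0,
    beta: float = 0.5,
    beta_sd: float = 0.0,
    noise_sd: float = 0.5,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> SimulatedCohort:
    """One-call cohort: panel, genotypes, truth, abundances and read counts.

    Stage sub-seeds are split deterministically from ``seed``.
    """
    panel = simulate_gene_panel(
        n_genes, frac_coding=frac_coding, abundance_sdlog=abundance_sdlog, seed=_sub(seed, 0)
    )
    genotypes = simulate_genotypes(
        n_samples, snps_per_gene, panel, maf_range=maf_range, seed=_sub(seed, 1)
    )
    truth = simulate_truth(
        panel,
        genotypes,
        frac_egenes=frac_egenes,
        beta=beta,
        beta_sd=beta_sd,
        noise_sd=noise_sd,
        seed=_sub(seed, 2),
    )
    abundance = simulate_expression(panel, genotypes, truth, seed=_sub(seed, 3))
    libs = simulate_library_sizes(
        n_samples, target_coverage_million, sd_million=coverage_sd_million, seed=_sub(seed, 4)
    )
    counts = simulate_reads(
        abundance, panel, libs, seed=_sub(seed, 5), sample_id=genotypes.sample_id
    )
    return SimulatedCohort(panel, genotypes, truth, abundance, counts)


def _sub(seed: int, stage: int) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))
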