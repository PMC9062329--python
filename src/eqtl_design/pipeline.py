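"""End-to-end orchestration: simulate -> downsample/quantify -> map -> fit -> design.

A run is fully described by a :class:`RunConfig` (serializable to YAML);
rerunning the same config reproduces every output bit-for-bit. Each stage
writes plain-text artifacts into the output directory, and the final
manifest records file paths, the config hash, and summary metrics (eGene
counts and mean R2 per coverage, the optimal design point).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import io
from .design import CostModel, MappingModel, effective_curve, optimize_coverage
from .errors import DependencyError
from .mapping import map_cis_eqtls
from .quantify import coverage_response_table, CoverageResponsePoint, fit_coverage_response
from .sim import _sub, simulate_cohort

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """All knobs of one pipeline run. Defaults give a ~2-minute desk-scale demo."""

    seed: int = 1
    outdir: str = "runs/demo"
    log_level: str = "INFO"
    # simulate
    n_genes: int = 200
    n_samples: int = 150
    snps_per_gene: int = 8
    frac_coding: float = 0.5
    abundance_sdlog: float = 2.0
    frac_egenes: float = 0.5
    beta: float = 0.5
    beta_sd: float = 0.0
    noise_sd: float = 0.5
    maf_lo: float = 0.05
    maf_hi: float = 0.5
    full_coverage: float = 50.0          # nominal million reads/sample
    transcriptome_scale: float | None = None  # defaults to n_genes / 45910
    # downsample / quantify
    coverage_grid: tuple = (1.0, 5.0, 10.0, 25.0, 50.0)
    n_replicates: int = 5
    # eQTL mapping
    window_bp: int = 1_000_000
    n_perm: int = 1000
    fdr: float = 0.05
    tpm_threshold: float = 0.1
    tpm_fraction: float = 0.2
    n_geno_pcs: int = 3
    n_expr_pcs: int = 10
    # curve / design
    mapping_rate: float = 1.0
    cost: dict = dataclasses.field(
        default_factory=lambda: {
            "library_prep": 87.0,
            "lane_cost": 1790.0,
            "reads_per_lane": 300.0,
            "extraction": 0.0,
            "genotyping": 53.0,
            "fixed": 0.0,
            "budget": 300_000.0,
        }
    )
    design_grid_start: float = 1.0
    design_grid_stop: float = 60.0
    design_grid_step: float = 0.5

    @property
    def scale(self) -> float:
        """Library-size scale: the panel's share of a 45,910-gene transcriptome."""
        return self.transcriptome_scale if self.transcriptome_scale else self.n_genes / 45_910

    def reads_at(self, coverage_million: float) -> float:
        """Actual simulated million reads/sample at a nominal coverage."""
        return coverage_million * self.scale

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coverage_grid"] = list(self.coverage_grid)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "coverage_grid" in d:
            d = dict(d)
            d["coverage_grid"] = tuple(d["coverage_grid"])
        return cls(**d)

    def hash(self) -> str:
        """Hash of the run-defining parameters (output location and log
        verbosity excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cost_model(self) -> CostModel:
        return CostModel(**self.cost)


def _paths(outdir: Path) -> dict:
    return {
        "config": outdir / "config.yaml",
        "panel": outdir / "gene_panel.tsv",
        "dosages": outdir / "dosages.tsv",
        "vcf": outdir / "genotypes.vcf",
        "truth": outdir / "truth.tsv",
        "counts": outdir / "counts.tsv",
        "response": outdir / "coverage_response.tsv",
        "curve": outdir / "curve.yaml",
        "egenes_full": outdir / "egenes_full.tsv",
        "egene_counts": outdir / "egene_counts.tsv",
        "design_points": outdir / "design_points.tsv",
        "optimal": outdir / "optimal_design.json",
        "manifest": outdir / "manifest.json",
    }


def stage_simulate(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = _paths(outdir)
    cohort = simulate_cohort(
        n_genes=config.n_genes,
        n_samples=config.n_samples,
        snps_per_gene=config.snps_per_gene,
        target_coverage_million=config.reads_at(config.full_coverage),
        frac_coding=config.frac_coding,
        abundance_sdlog=config.abundance_sdlog,
        frac_egenes=config.frac_egenes,
        beta=config.beta,
        beta_sd=config.beta_sd,
        noise_sd=config.noise_sd,
        maf_range=(config.maf_lo, config.maf_hi),
        seed=config.seed,
    )
    io.write_gene_panel(cohort.panel, paths["panel"])
    io.write_dosages(cohort.genotypes, paths["dosages"])
    io.write_vcf(cohort.genotypes, paths["vcf"])
    io.write_truth(cohort.truth, paths["truth"])
    io.write_counts(cohort.counts, paths["counts"])
    config.to_yaml(paths["config"])
    logger.info(
        "simulate: %d genes x %d samples, %.3fM mean mapped reads/sample",
        config.n_genes,
        config.n_samples,
        float(cohort.counts.library_size.mean()),
    )
    return {k: str(paths[k]) for k in ("panel", "dosages", "vcf", "truth", "counts")}


def stage_quantify(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    paths = _paths(outdir)
    io.ensure_exists(paths["counts"], "quantify", "simulate")
    io.ensure_exists(paths["panel"], "quantify", "simulate")
    counts = io.read_counts(paths["counts"])
    panel = io.read_gene_panel(paths["panel"])
    grid = [config.reads_at(c) for c in config.coverage_grid]
    _, table = coverage_response_table(
        counts, panel, grid, n_replicates=config.n_replicates, seed=_sub(config.seed, 10)
    )
    # report nominal coverages, not scaled library sizes
    table = table.copy()
    table["coverage"] = np.repeat(list(config.coverage_grid), config.n_replicates)
    table.to_csv(paths["response"], sep="\t", index=False)
    logger.info("quantify: %d response points", len(table))
    return {"response": str(paths["response"])}


def stage_fit_curve(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    paths = _paths(outdir)
    io.ensure_exists(paths["response"], "fit-curve", "quantify")
    import pandas as pd

    table = pd.read_csv(paths["response"], sep="\t")
    points = [
        CoverageResponsePoint(
            coverage=row.coverage,
            replicate_id=int(row.replicate),
            per_gene_r2=np.array([]),
            mean_r2=row.mean_r2,
            n_excluded=int(row.n_excluded),
        )
        for row in table.itertuples()
    ]
    curve = fit_coverage_response(points, mapping_rate=config.mapping_rate)
    io.write_curve(curve, paths["curve"])
    logger.info("fit-curve: alpha=%.4f beta_ln=%.4f", curve.alpha, curve.beta_ln)
    return {"curve": str(paths["curve"])}


def stage_map_eqtl(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    paths = _paths(outdir)
    io.ensure_exists(paths["counts"], "map-eqtl", "simulate")
    io.ensure_exists(paths["panel"], "map-eqtl", "simulate")
    io.ensure_exists(paths["dosages"], "map-eqtl", "simulate")
    counts = io.read_counts(paths["counts"])
    panel = io.read_gene_panel(paths["panel"])
    genotypes = io.read_dosages(paths["dosages"])
    from .quantify import downsample_counts

    results = []
    t0 = time.time()
    full = map_cis_eqtls(
        panel,
        genotypes,
        counts=counts,
        window_bp=config.window_bp,
        n_geno_pcs=config.n_geno_pcs,
        n_expr_pcs=config.n_expr_pcs,
        tpm_threshold=config.tpm_threshold,
        tpm_fraction=config.tpm_fraction,
        n_perm=config.n_perm,
        fdr_level=config.fdr,
        seed=_sub(config.seed, 20),
    )
    io.write_egenes(full.table, paths["egenes_full"])
    results.append({"coverage": config.full_coverage, "n_egenes": full.n_egenes})
    for ci, cov in enumerate(config.coverage_grid):
        if cov >= config.full_coverage:
            continue
        thinned = downsample_counts(
            counts,
            config.reads_at(cov),
            n_replicates=1,
            seed=_sub(config.seed, 30 + ci),
            allow_partial=True,
        )[0]
        res = map_cis_eqtls(
            panel,
            genotypes,
            counts=thinned,
            window_bp=config.window_bp,
            n_geno_pcs=config.n_geno_pcs,
            n_expr_pcs=config.n_expr_pcs,
            tpm_threshold=config.tpm_threshold,
            tpm_fraction=config.tpm_fraction,
            n_perm=config.n_perm,
            fdr_level=config.fdr,
            seed=_sub(config.seed, 20),
        )
        results.append({"coverage": cov, "n_egenes": res.n_egenes})
    import pandas as pd

    pd.DataFrame(sorted(results, key=lambda r: r["coverage"])).to_csv(
        paths["egene_counts"], sep="\t", index=False
    )
    logger.info("map-eqtl: %d coverage levels in %.1fs", len(results), time.time() - t0)
    return {"egenes_full": str(paths["egenes_full"]), "egene_counts": str(paths["egene_counts"])}


def stage_design(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    paths = _paths(outdir)
    io.ensure_exists(paths["curve"], "design", "fit-curve")
    curve = io.read_curve(paths["curve"])
    grid = np.round(
        np.arange(
            config.design_grid_start,
            config.design_grid_stop + config.design_grid_step / 2,
            config.design_grid_step,
        ),
        6,
    )
    frontier = effective_curve(
        config.cost_model(), curve, MappingModel(config.mapping_rate), grid
    )
    frontier.to_csv(paths["design_points"], sep="\t", index=False)
    best = optimize_coverage(frontier)
    with open(paths["optimal"], "w") as fh:
        json.dump(dataclasses.asdict(best), fh, indent=2)
    logger.info("design: optimum at b=%.1fM, N=%d, Neff=%.1f", best.b, best.n, best.n_eff)
    return {"design_points": str(paths["design_points"]), "optimal": str(paths["optimal"])}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order and write the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.time()
    files: dict = {}
    files.update(stage_simulate(config))
    files.update(stage_quantify(config))
    files.update(stage_fit_curve(config))
    files.update(stage_map_eqtl(config))
    files.update(stage_design(config))
    import pandas as pd

    response = pd.read_csv(files["response"], sep="\t")
    mean_r2 = (
        response.groupby("coverage")["mean_r2"].mean().round(6).to_dict()
    )
    egene_counts = pd.read_csv(files["egene_counts"], sep="\t")
    with open(files["optimal"]) as fh:
        optimal = json.load(fh)
    manifest = {
        "config_hash": config.hash(),
        "files": files,
        "summary": {
            "mean_r2_per_coverage": {str(k): v for k, v in mean_r2.items()},
            "egenes_per_coverage": {
                str(row.coverage): int(row.n_egenes) for row in egene_counts.itertuples()
            },
            "optimal_design": optimal,
        },
        "wall_time_s": round(time.time() - t0, 2),
    }
    paths = _paths(outdir)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete in %.1fs", manifest["wall_time_s"])
    return manifest
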