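"""Plain-text readers and writers for every artifact the pipeline produces.

All tables are tab-separated with a header row; coordinates are 1-based.
Genotypes can be written both as a dosage TSV and as a minimal unphased VCF
(GT field only). Every writer has a matching reader that round-trips the
container without loss.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quantify import CoverageResponseCurve, ExpressionMatrix
from .sim import EqtlTruth, GenePanel, GenotypePanel, ReadCountMatrix


def write_gene_panel(panel: GenePanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_panel(path) -> GenePanel:
    return GenePanel.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_truth(truth: EqtlTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path) -> EqtlTruth:
    return EqtlTruth.from_frame(pd.read_csv(path, sep="\t", dtype={"causal_snp_id": str}))


def write_dosages(genotypes: GenotypePanel, path) -> None:
    """SNP-per-row dosage TSV: snp_id, chrom, pos, maf, then one column per sample."""
    df = pd.DataFrame(
        {
            "snp_id": genotypes.snp_id,
            "chrom": genotypes.chrom,
            "pos": genotypes.snp_pos,
            "maf": genotypes.maf,
        }
    )
    dos = pd.DataFrame(genotypes.dosages.T, columns=genotypes.sample_id)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosages(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["snp_id", "chrom", "pos", "maf"]
    samples = [c for c in df.columns if c not in meta]
    return GenotypePanel(
        dosages=df[samples].to_numpy(dtype=np.int8).T,
        snp_id=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        snp_pos=df["pos"].to_numpy(),
        maf=df["maf"].to_numpy(dtype=float),
        sample_id=np.array(samples, dtype=object),
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypePanel, path) -> None:
    """Minimal VCFv4.2 with unphased GT calls (REF=A, ALT=G placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=eqtl-design synthetic genotypes\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.sample_id))
            + "\n"
        )
        for j in range(genotypes.n_snps):
            calls = "\t".join(_GT[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.snp_pos[j]}\t{genotypes.snp_id[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf_dosages(path) -> GenotypePanel:
    """Read a minimal GT-only VCF back into a GenotypePanel (alt-allele dosage)."""
    rows, ids, chroms, pos = [], [], [], []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chroms.append(parts[0])
            pos.append(int(parts[1]))
            ids.append(parts[2])
            rows.append([gt.count("1") for gt in parts[9:]])
    dosages = np.array(rows, dtype=np.int8).T
    af = dosages.mean(axis=0) / 2.0
    maf = np.clip(np.minimum(af, 1 - af), 1e-6, 0.5)
    return GenotypePanel(
        dosages=dosages,
        snp_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        snp_pos=np.array(pos),
        maf=maf,
        sample_id=np.array(samples, dtype=object),
    )


def write_counts(counts: ReadCountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c != "gene_id"]
    return ReadCountMatrix(
        counts=df[samples].to_numpy(dtype=np.int64),
        gene_id=df["gene_id"].to_numpy(dtype=object),
        sample_id=np.array(samples, dtype=object),
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression(path, unit: str = "tpm") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c != "gene_id"]
    return ExpressionMatrix(
        values=df[samples].to_numpy(dtype=float),
        gene_id=df["gene_id"].to_numpy(dtype=object),
        sample_id=np.array(samples, dtype=object),
        unit=unit,
    )


def write_curve(curve: CoverageResponseCurve, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(curve.to_dict(), fh, sort_keys=True)


def read_curve(path) -> CoverageResponseCurve:
    with open(path) as fh:
        return CoverageResponseCurve.from_dict(yaml.safe_load(fh))


def write_egenes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_egenes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_exists(path, stage: str, produced_by: str):
    """Raise a DependencyError naming the stage if an upstream file is missing."""
    from .errors import DependencyError

    p = Path(path)
    if not p.exists():
        raise DependencyError(
            f"stage '{stage}' requires '{p}', which is missing — run '{produced_by}' first"
        )
    return p
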