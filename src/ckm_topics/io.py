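"""Readers and writers for the pipeline's plain-text artifact formats.

Phenotypes travel as CSV (empty field = missing), genotypes as an
unphased-GT VCF plus a transposed dosage TSV (variants x participants),
platform labels as a two-column TSV, and ground truth as JSON + TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GeneticEffect, GenotypeMatrix, TruthRecord

__all__ = [
    "write_cohort_csv", "read_cohort_csv",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_platforms_tsv", "read_platforms_tsv",
    "write_vcf", "read_vcf",
    "write_truth", "read_truth",
    "write_genotypes",
]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    """Transposed dosage table: one row per variant, columns = participants."""
    n = geno.dosages.shape[0]
    df = pd.DataFrame(
        geno.dosages.T,
        index=geno.variants["id"],
        columns=[f"P{i}" for i in range(n)],
    )
    meta = geno.variants.set_index("id")
    out = pd.concat([meta, df], axis=1)
    out.to_csv(path, sep="\t", index_label="id")


def read_dosage_tsv(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Returns (dosages (n, m), variants DataFrame)."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "ea", "nea", "maf"]
    variants = df[meta_cols].copy()
    dos = df.drop(columns=meta_cols).to_numpy(dtype=np.int8).T
    return dos, variants


def write_platforms_tsv(platforms: np.ndarray, path) -> None:
    pd.DataFrame({
        "participant_id": np.arange(len(platforms)),
        "platform": platforms,
    }).to_csv(path, sep="\t", index=False)


def read_platforms_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["platform"].to_numpy()


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with unphased GT fields derived from dosages."""
    n = geno.dosages.shape[0]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(geno.variants["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        samples = "\t".join(f"P{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        order = geno.variants.sort_values(["chrom", "pos"]).index
        for j in order:
            row = geno.variants.loc[j]
            gts = "\t".join(gt_map[int(d)] for d in geno.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['nea']}"
                     f"\t{row['ea']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read GT dosages (ALT-allele count) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, meta = [], []
    for var in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dos = np.array([{0: 0, 1: 1, 3: 2}.get(t, -1) for t in var.gt_types],
                       dtype=np.int8)
        rows.append(dos)
        meta.append({"id": var.ID, "chrom": int(var.CHROM), "pos": var.POS,
                     "ea": var.ALT[0], "nea": var.REF})
    return np.array(rows, dtype=np.int8).T, pd.DataFrame(meta)


def write_genotypes(geno: GenotypeMatrix, outdir) -> None:
    outdir = Path(outdir)
    write_dosage_tsv(geno, outdir / "dosages.tsv")
    write_platforms_tsv(geno.platforms, outdir / "platforms.tsv")
    write_vcf(geno, outdir / "genotypes.vcf")


def write_truth(truth: TruthRecord, outdir) -> None:
    outdir = Path(outdir)
    pd.DataFrame(truth.true_phi).to_csv(outdir / "truth_phi.tsv", sep="\t", index=False)
    pd.DataFrame(truth.true_theta).to_csv(outdir / "truth_theta.tsv", sep="\t", index=False)
    pd.DataFrame(truth.missing_mask.astype(int)).to_csv(
        outdir / "truth_missing_mask.tsv", sep="\t", index=False)
    meta = {
        "disease_weights": {k: list(map(float, v))
                            for k, v in truth.disease_weights.items()},
        "genetic_effects": [
            {"variant": e.variant, "topic": e.topic, "gamma": e.gamma}
            for e in truth.genetic_effects
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=1))


def read_truth(outdir) -> TruthRecord:
    outdir = Path(outdir)
    meta = json.loads((outdir / "truth.json").read_text())
    return TruthRecord(
        true_phi=pd.read_csv(outdir / "truth_phi.tsv", sep="\t").to_numpy(),
        true_theta=pd.read_csv(outdir / "truth_theta.tsv", sep="\t").to_numpy(),
        disease_weights={k: np.asarray(v) for k, v in meta["disease_weights"].items()},
        genetic_effects=[GeneticEffect(**e) for e in meta["genetic_effects"]],
        missing_mask=pd.read_csv(outdir / "truth_missing_mask.tsv", sep="\t")
        .to_numpy().astype(bool),
    )
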