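"""Readers and writers for the pipeline's external formats.

Standard formats are used where one exists: genotypes as VCF (GT:DS) or a
plain dosage table, gene models as BED6. Bespoke tables (feature tables,
protein matrices, recombination maps, annotation and catalog tables, reports)
are tab-delimited with '#'-prefixed header lines naming the producing stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FEATURE_COLUMNS, GenotypeMatrix, ProteinMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_dosage_table",
    "read_feature_table",
    "write_feature_table",
    "read_gene_models_bed",
    "write_gene_models_bed",
    "read_recomb_map",
    "write_tsv",
    "read_protein_matrix",
    "write_protein_matrix",
]


def write_tsv(frame: pd.DataFrame, path, stage: str = "", index: bool = False) -> None:
    """Write a tab-delimited table with a '#'-prefixed provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        if stage:
            fh.write(f"# produced by pqtlkit stage: {stage}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_dosage_table(genotypes: GenotypeMatrix, path) -> None:
    """Dosage matrix as TSV: variant metadata columns then one column per individual."""
    meta = genotypes.variants[["chrom", "pos", "ref", "alt"]].copy()
    out = pd.concat([meta, genotypes.dosages.T], axis=1)
    out.index.name = "variant_id"
    write_tsv(out.reset_index(), path, stage="genotypes")


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write genotypes as an uncompressed VCF with GT and DS fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Mean dosage">\n'
        )
        for chrom in genotypes.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(genotypes.individuals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        D = genotypes.dosages.to_numpy()
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (vid, row) in enumerate(genotypes.variants.iterrows()):
            calls = []
            for d in D[:, j]:
                if np.isnan(d):
                    calls.append("./.:.")
                else:
                    calls.append(f"{gts[int(np.clip(round(d), 0, 2))]}:{d:.4f}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT:DS\t" + "\t".join(calls) + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    dosage_rows = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            row = ds[:, 0].astype(float)
        else:
            # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            gt = np.asarray(var.gt_types)
            row = np.where(gt == 3, 2.0, gt.astype(float))
            row[gt == 2] = np.nan
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dosage_rows.append(row)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="variant_id"),
    )
    dosages = pd.DataFrame(
        np.array(dosage_rows).T if dosage_rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="individual_id"),
        columns=variants.index,
    )
    gm = GenotypeMatrix(dosages, variants)
    gm.variants.attrs["n_multiallelic_skipped"] = n_multiallelic
    return gm


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF (DS preferred, else GT counts) or dosage TSV.

    Multi-allelic VCF records are skipped; the count is recorded in
    ``variants.attrs['n_multiallelic_skipped']``.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "dosage-table"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-table":
        table = _read_tsv(path, index_col="variant_id")
        meta_cols = ["chrom", "pos", "ref", "alt"]
        variants = table[meta_cols].copy()
        dosages = table.drop(columns=meta_cols).T.astype(float)
        dosages.index.name = "individual_id"
        return GenotypeMatrix(dosages, variants)
    raise ValueError(f"unknown genotype format {format!r}")


def write_feature_table(features: pd.DataFrame, path) -> None:
    write_tsv(features[FEATURE_COLUMNS], path, stage="synthetic_features")


def read_feature_table(path) -> pd.DataFrame:
    table = _read_tsv(path)
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return table


def write_gene_models_bed(gene_models: pd.DataFrame, path) -> None:
    """Gene models as BED6 (0-based half-open, name = trait id)."""
    start = np.minimum(gene_models["tss"], gene_models["tes"]) - 1
    end = np.maximum(gene_models["tss"], gene_models["tes"])
    bed = pd.DataFrame(
        {
            "chrom": gene_models["chrom"],
            "start": start.astype(int),
            "end": end.astype(int),
            "name": gene_models.index,
            "score": 0,
            "strand": gene_models["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_models_bed(path) -> pd.DataFrame:
    """BED6 -> gene models with TSS/TES in transcription orientation."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    tss = np.where(bed["strand"] == "-", bed["end"], bed["start"] + 1)
    tes = np.where(bed["strand"] == "-", bed["start"] + 1, bed["end"])
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "tss": tss,
            "tes": tes,
            "strand": bed["strand"],
        },
        index=pd.Index(bed["name"], name="trait_id"),
    )


def read_recomb_map(path) -> pd.DataFrame:
    table = _read_tsv(path)
    need = {"chrom", "pos", "rate_cm_mb"}
    if not need <= set(table.columns):
        raise ValueError(f"recombination map needs columns {sorted(need)}")
    return table


def write_protein_matrix(matrix: ProteinMatrix, prefix) -> None:
    """Protein matrix as TSV (rows = individual x bio replicate) plus a
    trait-metadata sidecar ``<prefix>.traits.tsv``."""
    prefix = Path(prefix)
    write_tsv(
        matrix.replicate_values.reset_index(),
        prefix.with_suffix(".tsv"),
        stage="array_quant",
    )
    write_tsv(
        matrix.trait_info.reset_index(),
        prefix.with_suffix(".traits.tsv"),
        stage="array_quant",
    )


def read_protein_matrix(prefix) -> ProteinMatrix:
    prefix = Path(prefix)
    rep = _read_tsv(prefix.with_suffix(".tsv")).set_index(
        ["individual_id", "bio_rep"]
    )
    rep.columns.name = "trait_id"
    info = _read_tsv(prefix.with_suffix(".traits.tsv")).set_index("trait_id")
    return ProteinMatrix(rep, info)
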