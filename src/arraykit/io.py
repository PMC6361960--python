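"""Readers and writers for the formats the toolkit touches.

Panels and genotypes travel as VCF 4.2 (read through cyvcf2; written as
plain text so fixtures stay human-readable).  Manifests, annotations,
phenotypes, summary statistics and association catalogs are TSV.  The
threshold configuration round-trips through a flat YAML mapping.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .core import (
    MISSING,
    AnnotationRecord,
    AnnotationTable,
    ArrayManifest,
    GenotypeMatrix,
    HaplotypePanel,
    ManifestEntry,
    ThresholdConfig,
    VariantRecord,
    variant_key,
)

__all__ = [
    "load_panel",
    "write_panel",
    "load_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_manifest",
    "write_manifest",
    "read_annotations",
    "write_annotations",
    "read_config",
    "write_config",
]

_MANIFEST_COLUMNS = ["id", "chrom", "pos", "alleleA", "alleleB", "categories", "provenance"]


def _vcf_header(sample_ids: Sequence[str], chroms: Sequence[str]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    seen = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    for c in seen:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    return "\n".join(lines) + "\n"


def _read_vcf_records(path: str):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    records = list(vcf)
    vcf.close()
    if not records:
        raise ValueError(f"{path}: VCF has no variant records")
    return samples, records


def load_panel(path: str) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Every GT must be phased and non-missing; the first offending record is
    named in the error.  Multi-allelic records are rejected.
    """
    samples, records = _read_vcf_records(path)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in records:
        if len(rec.ALT) != 1:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} is not biallelic")
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"unphased input: missing genotype at {rec.CHROM}:{rec.POS} (sample {samples[i]})"
                )
            if not phased:
                raise ValueError(
                    f"unphased input: genotype at {rec.CHROM}:{rec.POS} (sample {samples[i]}) is not phased"
                )
            col[2 * i] = a0
            col[2 * i + 1] = a1
        variants.append(VariantRecord(id=rec.ID or f"{rec.CHROM}:{rec.POS}", chrom=rec.CHROM,
                                      pos=rec.POS, alleleA=rec.REF, alleleB=rec.ALT[0]))
        columns.append(col)
    return HaplotypePanel(variants=variants, sample_ids=samples,
                          haplotypes=np.column_stack(columns))


def write_panel(panel: HaplotypePanel, path: str) -> None:
    """Write a panel as a phased plain-text VCF."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(panel.sample_ids, [v.chrom for v in panel.variants]))
        H = panel.haplotypes
        for j, v in enumerate(panel.variants):
            gts = "\t".join(f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(panel.n_samples))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.alleleA}\t{v.alleleB}\t.\tPASS\t.\tGT\t{gts}\n")


def _genotypes_from_vcf(path: str) -> GenotypeMatrix:
    samples, records = _read_vcf_records(path)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in records:
        if len(rec.ALT) != 1:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} is not biallelic")
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a0, a1 = gt[0], gt[1]
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        if len(col) != len(samples):
            raise ValueError(f"{path}: sample-count mismatch at {rec.CHROM}:{rec.POS}")
        variants.append(VariantRecord(id=rec.ID or f"{rec.CHROM}:{rec.POS}", chrom=rec.CHROM,
                                      pos=rec.POS, alleleA=rec.REF, alleleB=rec.ALT[0]))
        columns.append(col)
    return GenotypeMatrix(variants=variants, sample_ids=samples, calls=np.column_stack(columns))


def _genotypes_from_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"{path}: no variant rows")
    meta = ["id", "chrom", "pos", "alleleA", "alleleB"]
    missing_cols = [c for c in meta if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    sample_ids = [c for c in df.columns if c not in meta]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    variants = [VariantRecord(id=str(r.id), chrom=str(r.chrom), pos=int(r.pos),
                              alleleA=str(r.alleleA), alleleB=str(r.alleleB))
                for r in df.itertuples()]
    calls = df[sample_ids].to_numpy(dtype=float)
    out = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(variants=variants, sample_ids=sample_ids, calls=out.T)


def load_genotypes(path: str) -> GenotypeMatrix:
    """Read hard calls from a VCF (GT may be unphased or missing) or a TSV.

    The TSV layout is ``id chrom pos alleleA alleleB <sample>...`` with calls
    0/1/2 and empty/NA for missing.
    """
    if str(path).endswith((".vcf", ".vcf.gz")):
        return _genotypes_from_vcf(path)
    return _genotypes_from_tsv(path)


def write_genotypes_vcf(geno: GenotypeMatrix, path: str) -> None:
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_vcf_header(geno.sample_ids, [v.chrom for v in geno.variants]))
        for j, v in enumerate(geno.variants):
            gts = "\t".join(gt_strings[int(c)] for c in geno.calls[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.alleleA}\t{v.alleleB}\t.\tPASS\t.\tGT\t{gts}\n")


def write_genotypes_tsv(geno: GenotypeMatrix, path: str) -> None:
    data = {
        "id": [v.id for v in geno.variants],
        "chrom": [v.chrom for v in geno.variants],
        "pos": [v.pos for v in geno.variants],
        "alleleA": [v.alleleA for v in geno.variants],
        "alleleB": [v.alleleB for v in geno.variants],
    }
    calls = geno.calls.astype(object).T  # variants x samples
    calls[calls == MISSING] = "NA"
    df = pd.concat([pd.DataFrame(data),
                    pd.DataFrame(calls, columns=list(geno.sample_ids))], axis=1)
    df.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: ArrayManifest, path: str) -> None:
    rows = []
    for e in manifest.entries:
        v = e.variant
        rows.append({
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "alleleA": v.alleleA, "alleleB": v.alleleB,
            "categories": ";".join(sorted(e.categories)),
            "provenance": e.provenance,
        })
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> ArrayManifest:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    manifest = ArrayManifest()
    for r in df.itertuples():
        variant = VariantRecord(id=str(r.id), chrom=str(r.chrom), pos=int(r.pos),
                                alleleA=str(r.alleleA), alleleB=str(r.alleleB))
        cats = set(str(r.categories).split(";")) if r.categories else set()
        # ManifestEntry validates category labels and raises with the allowed set
        manifest.add(ManifestEntry(variant=variant, categories=cats, provenance=str(r.provenance)))
    return manifest


def write_annotations(records: Sequence[AnnotationRecord],
                      variants_by_key: Mapping[tuple, VariantRecord], path: str) -> None:
    pops = sorted({p for r in records for p in r.pop_maf})
    rows = []
    for r in records:
        v = variants_by_key[r.key]
        row = {
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "alleleA": v.alleleA, "alleleB": v.alleleB,
            "consequence": r.consequence,
            "sift_damaging": int(r.sift_damaging),
            "polyphen_hdiv_damaging": int(r.polyphen_hdiv_damaging),
            "polyphen_hvar_damaging": int(r.polyphen_hvar_damaging),
        }
        for p in pops:
            row[f"maf_{p}"] = r.pop_maf.get(p, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pops = [c[4:] for c in df.columns if c.startswith("maf_")]
    records = []
    for r in df.itertuples():
        maf = {}
        for p in pops:
            val = getattr(r, f"maf_{p}")
            if pd.notna(val):
                maf[p] = float(val)
        records.append(AnnotationRecord(
            key=variant_key(str(r.chrom), int(r.pos), str(r.alleleA), str(r.alleleB)),
            consequence=str(r.consequence),
            sift_damaging=bool(int(r.sift_damaging)),
            polyphen_hdiv_damaging=bool(int(r.polyphen_hdiv_damaging)),
            polyphen_hvar_damaging=bool(int(r.polyphen_hvar_damaging)),
            pop_maf=maf,
        ))
    return AnnotationTable(records)


def write_config(cfg: ThresholdConfig, path: str) -> None:
    payload = {name: getattr(cfg, name) for name in ThresholdConfig.field_names()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_config(path: str) -> ThresholdConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    unknown = set(payload) - set(ThresholdConfig.field_names())
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return ThresholdConfig(**payload)
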