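"""Readers and writers: per-line VCFs, TSV tables, repetitive-region masking."""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .config import AnalysisConfig
from .model import DepthTable, LineGenotypes, MultiLineCohort, RecombinationMap, VariantKey

logger = logging.getLogger(__name__)


def _read_line_vcf(path: str, impute_missing: bool) -> tuple[list[VariantKey], list[str], np.ndarray]:
    """Read one line's VCF into (variants, individuals, dosage matrix).

    Dosage comes from the DS FORMAT field when present, otherwise from GT
    hard calls coded 0/1/2. Multiallelic records are rejected.
    """
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or drop it first"
            )
        key = VariantKey(str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0])
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
        else:
            row = np.asarray(rec.gt_types, dtype=float)
            row[row == 3] = np.nan  # 3 = missing under gts012
        bad = np.isnan(row)
        if bad.any():
            if not impute_missing:
                raise ValueError(
                    f"{path}: missing genotype at {key.variant_id}; the pipeline expects "
                    "fully imputed data (set impute_missing to mean-impute instead)"
                )
            if bad.all():
                raise ValueError(f"{path}: all genotypes missing at {key.variant_id}")
            row[bad] = row[~bad].mean()
        if row.min() < 0 or row.max() > 2:
            raise ValueError(f"{path}: dosage outside [0, 2] at {key.variant_id}")
        keys.append(key)
        rows.append(row)
    dosage = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return keys, samples, dosage


def load_cohort(
    paths: Sequence[str],
    line_ids: Sequence[str] | None = None,
    config: AnalysisConfig | None = None,
) -> MultiLineCohort:
    """Load one VCF per line and merge them on the union of variant sites.

    Sites absent from a line's VCF are marked absent (NaN) for that line,
    distinguishing "not called in this line" from "called, dosage 0".
    A site observed with conflicting REF alleles across files is a hard error.
    """
    config = config or AnalysisConfig()
    if line_ids is None:
        line_ids = [Path(p).name.removesuffix(".gz").removesuffix(".vcf") for p in paths]
    if len(line_ids) != len(paths):
        raise ValueError("line_ids and paths length mismatch")
    if len(set(line_ids)) != len(line_ids):
        raise ValueError(f"duplicate line ids: {line_ids}")

    per_line = {}
    ref_seen: dict[tuple[str, int], str] = {}
    for lid, path in zip(line_ids, paths):
        keys, samples, dosage = _read_line_vcf(path, config.impute_missing)
        for k in keys:
            prev = ref_seen.setdefault((k.chrom, k.pos), k.ref)
            if prev != k.ref:
                raise ValueError(
                    f"conflicting REF alleles at {k.chrom}:{k.pos}: {prev!r} vs {k.ref!r}"
                )
        per_line[lid] = (keys, samples, dosage)

    union = sorted({k for keys, _, _ in per_line.values() for k in keys}, key=VariantKey.sort_key)
    index = {k: i for i, k in enumerate(union)}

    lines = {}
    for lid, (keys, samples, dosage) in per_line.items():
        full = np.full((len(union), len(samples)), np.nan)
        idx = np.fromiter((index[k] for k in keys), dtype=int, count=len(keys))
        full[idx] = dosage
        lines[lid] = LineGenotypes(lid, samples, full)
    return MultiLineCohort(union, lines)


def write_vcf(
    path: str,
    variants: Iterable[VariantKey],
    individuals: Sequence[str],
    dosage: np.ndarray,
    called: np.ndarray | None = None,
) -> None:
    """Write a plain-text VCF 4.2 with GT (rounded hard call) and DS fields.

    Rows where ``called`` is False are omitted: the variant was not called in
    this line.
    """
    variants = list(variants)
    dosage = np.asarray(dosage, dtype=float)
    if called is None:
        called = np.isfinite(dosage).all(axis=1)
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=linevar\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternative allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(individuals) + "\n")
        gt_codes = ("0/0", "0/1", "1/1")
        for i, v in enumerate(variants):
            if not called[i]:
                continue
            cells = []
            for d in dosage[i]:
                state = 0 if d < 0.5 else (1 if d <= 1.5 else 2)
                cells.append(f"{gt_codes[state]}:{d:.6g}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def repetitive_mask(depths: DepthTable) -> np.ndarray:
    """True (exclude) where a variant's mean depth exceeds 3x the mean coverage.

    High-depth sites are treated as potential repetitive regions where reads
    from multiple genomic copies pile up; the inequality is strict, so a site
    at exactly 3x is retained.
    """
    return depths.depth > 3.0 * depths.mean_coverage


def write_table(
    records: pd.DataFrame,
    destination: str | os.PathLike,
    config: AnalysisConfig | None = None,
    extra_metadata: Sequence[str] = (),
) -> None:
    """Write a TSV with '#'-prefixed metadata lines and 6-significant-digit floats."""
    config = config or AnalysisConfig()
    dest = Path(destination)
    try:
        with open(dest, "w") as fh:
            for line in config.metadata_lines():
                fh.write(line + "\n")
            for line in extra_metadata:
                fh.write(f"# {line}\n")
            records.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise OSError(f"cannot write table to {dest}: {exc}") from exc


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_recombination_map(path: str) -> RecombinationMap:
    df = read_table(path)
    return RecombinationMap(df[["chrom", "start", "end", "rate"]].astype(
        {"chrom": str, "start": int, "end": int, "rate": float}
    ))


def read_depth_table(path: str) -> DepthTable:
    df = read_table(path)
    mean_cov = float(df["mean_coverage"].iloc[0])
    return DepthTable(df["depth"].to_numpy(float), mean_cov)


def read_phenotypes(path: str) -> pd.DataFrame:
    df = read_table(path)
    req = {"individual", "trait", "value"}
    if not req.issubset(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(req)}")
    return df
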