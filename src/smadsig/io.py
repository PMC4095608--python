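"""Readers and writers for every on-disk format the pipeline touches.

All text I/O is UTF-8 and tab-delimited; lines starting with ``#`` are
ignored.  Every reader/writer pair is a round-trip identity on valid input.
Readers never silently drop rows: whenever rows are collapsed or rejected a
warning reports the count.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneSignature,
    GenomicInterval,
    SignatureEntry,
    SurvivalCohort,
    TssRecord,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_survival_table",
    "write_survival_table",
    "read_regions_bed",
    "write_regions_bed",
    "read_signature_file",
    "write_signature_file",
    "read_tss_table",
    "write_tss_table",
    "read_fasta",
    "write_fasta",
    "load_config",
    "save_config",
]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")


def read_expression_table(path, annotation_path=None) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV.

    The first column holds gene ids, the header row sample ids.  Duplicate
    gene rows are collapsed to the row with the highest mean intensity (a
    common array-collapse rule); a warning reports how many were dropped.
    """
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            if not line.startswith("#") and line.strip():
                header = line.rstrip("\n").split("\t")
                break
    if header is None or len(header) < 2:
        raise ValueError(f"{path}: expression table needs a header with >= 2 columns")
    raw_samples = pd.Index(header[1:])
    dup_samples = raw_samples[raw_samples.duplicated()].unique()
    if len(dup_samples):
        raise ValueError(f"{path}: duplicate sample id(s) {list(dup_samples)}")
    raw = _read_tsv(path)
    sample_ids = list(raw.columns[1:])
    gene_col = raw.columns[0]
    try:
        values = raw[sample_ids].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    values.index = raw[gene_col].astype(str)
    values.index.name = gene_col
    if values.index.duplicated().any():
        n_in = len(values)
        order = values.mean(axis=1).to_numpy()
        values = (
            values.assign(_mean=order)
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        values = values.loc[sorted(values.index, key=list(raw[gene_col]).index)]
        warnings.warn(
            f"{path}: collapsed {n_in - len(values)} duplicate gene row(s) "
            "to the row with highest mean intensity"
        )
    annotations = None
    if annotation_path is not None:
        ann = _read_tsv(annotation_path)
        annotations = ann.set_index(ann.columns[0])
    return ExpressionMatrix(values, annotations)


def write_expression_table(matrix: ExpressionMatrix, path, annotation_path=None) -> None:
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", encoding="utf-8")
    if annotation_path is not None and matrix.sample_annotations is not None:
        ann = matrix.sample_annotations.copy()
        ann.index.name = ann.index.name or "sample"
        ann.to_csv(annotation_path, sep="\t", encoding="utf-8")


def read_survival_table(path) -> SurvivalCohort:
    """Read a survival TSV with columns sample, time, event, er_status, [covariates].

    Missing ``er_status`` cells are coded ``unknown`` explicitly.
    """
    raw = _read_tsv(path)
    required = {"sample", "time", "event"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: survival table lacks column(s) {sorted(missing)}")
    df = raw.set_index("sample")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(float)
    if not df["event"].isin([0.0, 1.0]).all():
        bad = df.index[~df["event"].isin([0.0, 1.0])].tolist()
        raise ValueError(f"{path}: event not in {{0,1}} for sample(s) {bad}")
    for col in df.columns:
        if col in ("time", "event", "er_status"):
            continue
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError):
            pass  # ordinal/categorical covariates stay as strings
    return SurvivalCohort(df)


def write_survival_table(cohort: SurvivalCohort, path) -> None:
    df = cohort.data.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", encoding="utf-8")


def write_regions_bed(regions, path) -> None:
    """Write binding-region calls as BED; the score column carries the statistic."""
    with open(path, "w", encoding="utf-8") as fh:
        for region in regions:
            iv = getattr(region, "interval", region)
            name = getattr(region, "name", "region")
            score = getattr(region, "statistic", 0.0)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:.6g}\t.\n")


def read_regions_bed(path) -> list[GenomicInterval]:
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            chrom, start, end = fields[0], fields[1], fields[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate {start!r}/{end!r}"
                ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start_i, end_i, strand))
    return intervals


_SIG_COLUMNS = ["gene", "weight", "in_vitro_direction", "in_vivo_direction", "concordance"]


def write_signature_file(signature: GeneSignature, path) -> None:
    rows = []
    for e in signature.entries:
        rows.append(
            {
                "gene": e.gene_id,
                "weight": e.weight,
                "in_vitro_direction": e.in_vitro_direction,
                "in_vivo_direction": "" if e.in_vivo_direction is None else e.in_vivo_direction,
                "concordance": "" if e.concordance is None else e.concordance,
            }
        )
    pd.DataFrame(rows, columns=_SIG_COLUMNS).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_signature_file(path) -> GeneSignature:
    raw = _read_tsv(path)
    if "gene" not in raw.columns or "weight" not in raw.columns:
        raise ValueError(f"{path}: signature file needs 'gene' and 'weight' columns")
    entries = []
    for _, row in raw.iterrows():
        try:
            weight = int(row["weight"])
            if float(row["weight"]) != weight:
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: weight for {row['gene']} must be the integer -1 or +1, "
                f"got {row['weight']!r}"
            ) from None
        in_vitro = int(row["in_vitro_direction"]) if _has(row, "in_vitro_direction") else 0
        in_vivo = int(float(row["in_vivo_direction"])) if _has(row, "in_vivo_direction") else None
        conc = row["concordance"] if _has(row, "concordance") else None
        entries.append(
            SignatureEntry(str(row["gene"]), weight, in_vitro, in_vivo, conc)
        )
    return GeneSignature(entries)


def _has(row, col) -> bool:
    return col in row.index and pd.notna(row[col]) and str(row[col]) != ""


def read_tss_table(path) -> list[TssRecord]:
    """Read a TSS TSV with columns gene, chrom, position, strand."""
    raw = _read_tsv(path)
    required = {"gene", "chrom", "position", "strand"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: TSS table lacks column(s) {sorted(missing)}")
    records = []
    for _, row in raw.iterrows():
        pos = int(row["position"])
        records.append(
            TssRecord(
                str(row["gene"]),
                GenomicInterval(str(row["chrom"]), pos, pos + 1, str(row["strand"])),
                str(row["strand"]),
            )
        )
    genes = [r.gene_id for r in records]
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene id(s) in TSS table: {dup}")
    return records


def write_tss_table(records, path) -> None:
    rows = [
        {"gene": r.gene_id, "chrom": r.interval.chrom, "position": r.position,
         "strand": r.strand}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_probe_table(panel, path) -> None:
    """Write a tiling probe panel: position plus one column per array."""
    import pandas as pd  # noqa: F811

    cols = {"chrom": panel.chrom, "position": panel.probe_positions}
    for r in range(panel.vehicle.shape[0]):
        cols[f"vehicle_{r + 1}"] = panel.vehicle[r]
    for r in range(panel.treated.shape[0]):
        cols[f"treated_{r + 1}"] = panel.treated[r]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_probe_table(path):
    """Read a tiling probe panel written by :func:`write_probe_table`."""
    from .peaks import ProbePanel

    raw = _read_tsv(path)
    required = {"chrom", "position"}
    if required - set(raw.columns):
        raise ValueError(f"{path}: probe table needs columns {sorted(required)}")
    chroms = raw["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: probe table must hold a single chromosome, got {list(chroms)}")
    vehicle_cols = sorted(c for c in raw.columns if c.startswith("vehicle_"))
    treated_cols = sorted(c for c in raw.columns if c.startswith("treated_"))
    if len(vehicle_cols) < 2 or len(treated_cols) < 2:
        raise ValueError(f"{path}: need >= 2 replicate columns per condition")
    return ProbePanel(
        str(chroms[0]),
        raw["position"].astype(int).to_numpy(),
        raw[vehicle_cols].astype(float).to_numpy().T,
        raw[treated_cols].astype(float).to_numpy().T,
    )


def read_fasta(path):
    """Read promoter sequences; returns a list of Bio.SeqRecord objects."""
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def load_config(path) -> AnalysisConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
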