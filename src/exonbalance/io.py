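"""Readers and writers for the tabular and interval formats the pipeline consumes.

All count matrices are plain TSV (features in the first column, one column per
sample); gene annotation is BED6 plus a biotype column, or GFF3. Internally
every interval is 0-based half-open (BED convention); user-facing reports are
1-based inclusive. This module contains no science.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_BIOTYPES = ("protein_coding", "lncRNA", "other")
VALID_STAGES = ("0", "I", "II", "III", "IV", "NA")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the declared format."""


class ValidationError(ValueError):
    """Raised when a parsed table violates a structural invariant."""


@dataclass
class CountTable:
    """An integer read-count matrix, features x samples.

    Wraps a pandas DataFrame whose index holds unique feature ids and whose
    columns hold unique sample ids; every cell is a non-negative integer.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count table")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count table")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric cells in count table")
        if arr.size:
            if np.any(~np.isfinite(arr)):
                raise ValidationError("missing or non-finite counts")
            if np.any(arr < 0):
                raise ValidationError("negative counts")
            if np.any(arr != np.floor(arr)):
                raise ValidationError("non-integer counts")
        self.counts = df.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class GeneAnnotationTable:
    """Gene locations and biotypes; coordinates 0-based half-open."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand, biotype

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand", "biotype")

    def __post_init__(self) -> None:
        df = self.genes
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in annotation")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()[:5]
            raise ValidationError(f"start >= end for genes {bad}")
        if (df["start"] < 0).any():
            raise ValidationError("negative start coordinate")
        unknown = ~df["biotype"].isin(VALID_BIOTYPES)
        if unknown.any():
            df = df.copy()
            df.loc[unknown, "biotype"] = "other"
        self.genes = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SampleMetadata:
    """Per-sample clinical annotation: stage, subtype, receptor status."""

    samples: pd.DataFrame  # columns: sample_id, stage, subtype, receptor_status

    def __post_init__(self) -> None:
        df = self.samples.copy()
        if "sample_id" not in df.columns:
            raise ValidationError("metadata missing sample_id column")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        for col in ("stage", "subtype", "receptor_status"):
            if col not in df.columns:
                df[col] = "NA"
        df["stage"] = df["stage"].astype(str).str.strip().replace({"nan": "NA", "": "NA"})
        bad = ~df["stage"].isin(VALID_STAGES)
        if bad.any():
            raise ValidationError(
                f"invalid stage values: {sorted(df.loc[bad, 'stage'].unique())}"
            )
        self.samples = df.reset_index(drop=True)

    def stage_of(self) -> pd.Series:
        return self.samples.set_index("sample_id")["stage"]


# ---------------------------------------------------------------------------
# Readers


def read_count_table(path: str, format: str = "tsv") -> CountTable:
    """Read a TSV count matrix (first column feature ids, header sample ids)."""
    if format != "tsv":
        raise FormatError(f"unknown count-table format {format!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError("count table has no sample columns")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample ids in count table header")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.columns = samples
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in count table: {exc}") from exc
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "feature_id"
    return CountTable(numeric)


def read_metadata(path: str) -> SampleMetadata:
    """Read a sample-metadata CSV."""
    df = pd.read_csv(path, dtype=str)
    return SampleMetadata(df)


def _parse_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 7:
                raise FormatError(f"{path}:{ln}: expected >=7 BED columns")
            chrom, start, end, name, _score, strand, biotype = parts[:7]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            rows.append((name, chrom, start_i, end_i, strand, biotype))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )


def _parse_gff3(path: str) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features(featuretype="gene"):
        biotype = (
            feat.attributes.get("gene_biotype") or feat.attributes.get("biotype") or ["other"]
        )[0]
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("gene_id") or [feat.id])[0]
        # gffutils keeps GFF3 1-based inclusive coordinates; convert to 0-based half-open
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand or ".", biotype))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )


def read_annotation(path: str, format: str = "bed") -> GeneAnnotationTable:
    """Read gene annotation from BED6+biotype or GFF3.

    BED input is kept 0-based half-open; GFF3 is converted from 1-based
    inclusive. Biotypes outside {protein_coding, lncRNA} map to "other".
    """
    if format in ("bed", "bed6+biotype"):
        df = _parse_bed(path)
    elif format == "gff3":
        df = _parse_gff3(path)
    else:
        raise FormatError(f"unknown annotation format {format!r}")
    return GeneAnnotationTable(df)


# ---------------------------------------------------------------------------
# Writers


def write_results(records: pd.DataFrame, path: str, float_sig: int = 6) -> None:
    """Write any result table as TSV with deterministic column order.

    Floats are rendered with `float_sig` significant digits so that a
    write/read round trip reproduces values to rendering precision.
    """
    dirname = os.path.dirname(os.path.abspath(path))
    os.makedirs(dirname, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tmp")
    os.close(fd)
    try:
        records.to_csv(tmp, sep="\t", index=False, float_format=f"%.{float_sig}g")
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_count_table(table: CountTable, path: str) -> None:
    df = table.counts.reset_index()
    df.columns = ["feature_id", *table.sample_ids]
    write_results(df, path)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def to_report_coords(df: pd.DataFrame) -> pd.DataFrame:
    """Convert internal 0-based half-open start/end to 1-based inclusive."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out
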