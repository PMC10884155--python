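"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: BED3 (fragments), narrowPeak (BED6+4 peaks), 10-column BEDPE
(enhancer-promoter pairs), and TSV tables for genes, expression and sample
sheets.  All coordinates are written and read as 0-based half-open.

Parsing errors raise :class:`FormatError` naming the file and line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal", "pvalue", "qvalue", "peak",
]
BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]
GENE_COLS = ["chrom", "tss", "strand", "gene_id", "body_start", "body_end"]


class FormatError(ValueError):
    """An input file violates its declared dialect."""


# ---------------------------------------------------------------- BED3

def read_bed3(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str, 1: np.int64, 2: np.int64})
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    except ValueError as exc:
        raise FormatError(f"{path}: not a valid BED3 file ({exc})") from exc
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED3 requires 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_bed3(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- narrowPeak

def read_narrowpeak(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a 10-column narrowPeak file into a peak table.

    The summit is returned as an absolute coordinate (start + offset); a
    missing summit offset (-1) falls back to the interval midpoint.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}: line {lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4])
                strand = fields[5]
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            summit = start + offset if offset >= 0 else (start + end) // 2
            rows.append((chrom, start, end, name, score, strand, signal, summit))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                     "strand", "signal", "summit"])
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64, "score": float,
                        "signal": float, "summit": np.int64})
    if sample_id is not None:
        df["sample_id"] = sample_id
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    """Write a peak table (chrom/start/end/summit/score[...]) as narrowPeak."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "name": df["name"] if "name" in df else [f"peak_{i}" for i in range(len(df))],
        "score": df["score"],
        "strand": df["strand"] if "strand" in df else ".",
        "signal": df["signal"] if "signal" in df else df["score"],
        "pvalue": -1,
        "qvalue": -1,
        "peak": (df["summit"] - df["start"]).astype(np.int64)
                if "summit" in df else (df["end"] - df["start"]) // 2,
    })
    if len(out):
        width = out["end"] - out["start"]
        if ((out["peak"] < 0) | (out["peak"] >= width)).any():
            raise ValueError("summit offset outside [0, width)")
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------- BEDPE

def read_bedpe(path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}: line {lineno}: BEDPE requires 10 columns, got {len(fields)}"
                )
            try:
                rows.append((
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3], int(fields[4]), int(fields[5]),
                    fields[6], float(fields[7]), fields[8], fields[9],
                ))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=BEDPE_COLS)
    if df.empty:
        df = df.astype({"start1": np.int64, "end1": np.int64,
                        "start2": np.int64, "end2": np.int64, "score": float})
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLS) + "\n")
        if len(df):
            df[BEDPE_COLS].to_csv(fh, sep="\t", header=False, index=False,
                                  float_format="%.8g")


# ---------------------------------------------------------------- TSV tables

def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = set(GENE_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gene table missing columns {sorted(missing)}")
    if len(df):
        inside = (df["body_start"] <= df["tss"]) & (df["tss"] < df["body_end"])
        if not inside.all():
            bad = df.loc[~inside, "gene_id"].iloc[0]
            raise FormatError(f"{path}: TSS outside gene body for {bad}")
        if not df["strand"].isin(["+", "-"]).all():
            raise FormatError(f"{path}: strand must be + or -")
    return df[GENE_COLS]


def write_genes(df: pd.DataFrame, path) -> None:
    df[GENE_COLS].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Gene x sample TPM matrix with gene_id as index."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "genotype", "stage"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet missing column {col!r}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df[["sample", "genotype", "stage"]].to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_genome(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": np.int64})
    if not {"chrom", "length"} <= set(df.columns):
        raise FormatError(f"{path}: genome table needs chrom and length columns")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_genome(genome: dict[str, int], path) -> None:
    pd.DataFrame({"chrom": list(genome), "length": list(genome.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_contact_table(path) -> pd.DataFrame:
    """Two-column (bin_start, contact) TSV for the binned contact model."""
    df = pd.read_csv(path, sep="\t")
    if not {"bin_start", "contact"} <= set(df.columns):
        raise FormatError(f"{path}: contact table needs bin_start and contact columns")
    return df
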