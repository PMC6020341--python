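"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals are 0-based half-open in memory (BED-native).
GTF records (1-based, closed) are converted on read and on write.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- counts

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x cell count matrix (first column gene_id, one column per cell)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------- GTF

def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read gene/exon records from a GTF into a 0-based half-open frame.

    Returns columns: chrom, source, feature, start, end, strand,
    gene_id, transcript_id (transcript_id empty for gene records).
    """
    import pyranges

    gr = pyranges.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    rename = {"Chromosome": "chrom", "Start": "start", "End": "end",
              "Strand": "strand", "Feature": "feature", "Source": "source"}
    df = df.rename(columns=rename)
    keep = ["chrom", "source", "feature", "start", "end", "strand",
            "gene_id", "transcript_id"]
    for col in keep:
        if col not in df.columns:
            df[col] = "" if col not in ("start", "end") else 0
    df = df[keep].copy()
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_gtf(records: pd.DataFrame, path: str | Path) -> None:
    """Write gene/exon records (0-based half-open in memory) as GTF (1-based closed)."""
    lines = []
    for row in records.itertuples(index=False):
        attrs = f'gene_id "{row.gene_id}";'
        tid = getattr(row, "transcript_id", "")
        if tid:
            attrs += f' transcript_id "{tid}";'
        lines.append("\t".join([
            str(row.chrom), getattr(row, "source", "cginoise") or "cginoise",
            row.feature, str(int(row.start) + 1), str(int(row.end)),
            ".", row.strand, ".", attrs,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4/BED6 file; returns chrom, start, end, name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols
    if "name" not in df.columns:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    df["chrom"] = df["chrom"].astype(str)
    return df[["chrom", "start", "end", "name"]]


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph track; returns chrom, start, end, value."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- tables

def read_table(path: str | Path, index_col: str = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index(index_col)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)
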