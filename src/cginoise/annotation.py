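"""Per-gene static promoter features from gene models, CpG islands and sequence.

Promoters span -1 kb to +500 bp around the transcriptional start site,
accounting for strand; CpG islands are assigned by interval overlap with
the promoter; GC content is computed over the promoter sequence.
All intervals are 0-based half-open.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_UP = 1000
PROMOTER_DOWN = 500
PROMOTER_WIDTH = PROMOTER_UP + PROMOTER_DOWN

CONTINUOUS_FEATURES = ("cgi_size_bp", "gc_fraction", "transcript_length_bp",
                       "n_exons", "mean_exon_length_bp")


# ---------------------------------------------------------------- promoters

def define_promoters(gene_models: pd.DataFrame) -> pd.DataFrame:
    """One promoter interval per gene from gene records.

    ``gene_models`` needs columns chrom, start, end, strand and either a
    ``tss`` column or feature == 'gene' rows (TSS = start on +, end - 1 on -,
    i.e. the 5'-most base of the gene record).  Promoters run [tss - 1000,
    tss + 500) on the + strand and mirrored on the - strand; intervals
    extending past position 0 are clipped and flagged.
    """
    df = gene_models
    if "feature" in df.columns:
        df = df[df["feature"] == "gene"]
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")

    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        logger.warning("define_promoters: dropping %d records without strand",
                       int(bad.sum()))
        df = df[~bad]

    if "tss" in df.columns:
        tss = df["tss"].astype(int)
    else:
        tss = df["start"].where(df["strand"] == "+", df["end"] - 1).astype(int)

    plus = df["strand"] == "+"
    start = np.where(plus, tss - PROMOTER_UP, tss - PROMOTER_DOWN)
    end = np.where(plus, tss + PROMOTER_DOWN, tss + PROMOTER_UP)
    clipped = start < 0
    start = np.maximum(start, 0)
    return pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "start": start.astype(int),
        "end": end.astype(int),
        "strand": df["strand"].to_numpy(),
        "tss": tss.to_numpy(),
        "clipped": clipped,
    }, index=df.index.rename("gene_id"))


# ---------------------------------------------------------------- structure

def gene_structure_features(gene_models: pd.DataFrame) -> pd.DataFrame:
    """Transcript length, exon count and mean exon length per gene.

    Uses the longest annotated transcript of each gene (transcript length =
    sum of its exon lengths).  Genes without exon records are omitted; the
    downstream join marks them missing rather than zero.
    """
    exons = gene_models[gene_models["feature"] == "exon"].copy()
    if exons.empty:
        return pd.DataFrame(columns=["transcript_length_bp", "n_exons",
                                     "mean_exon_length_bp"]
                            ).rename_axis("gene_id")
    exons["exon_len"] = exons["end"] - exons["start"]
    per_tx = exons.groupby(["gene_id", "transcript_id"]).agg(
        transcript_length_bp=("exon_len", "sum"),
        n_exons=("exon_len", "size"))
    # longest transcript per gene; deterministic tie-break on transcript id
    per_tx = per_tx.sort_values(
        ["transcript_length_bp", "transcript_id"],
        ascending=[False, True],
        key=lambda s: s if s.name == "transcript_length_bp" else s.astype(str))
    longest = per_tx.reset_index().drop_duplicates("gene_id").set_index("gene_id")
    longest["mean_exon_length_bp"] = (longest["transcript_length_bp"]
                                      / longest["n_exons"])
    return longest[["transcript_length_bp", "n_exons", "mean_exon_length_bp"]]


# ---------------------------------------------------------------- CGI overlap

def _best_overlap(starts: np.ndarray, ends: np.ndarray,
                  isl_start: np.ndarray, isl_end: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """For each query interval, the island with maximal overlap (ties -> longer).

    Returns (overlap_bp, island_length); zeros when no island overlaps.
    """
    ov = (np.minimum(ends[:, None], isl_end[None, :])
          - np.maximum(starts[:, None], isl_start[None, :]))
    ov = np.clip(ov, 0, None)
    lengths = (isl_end - isl_start)[None, :]
    # rank by (overlap, island length); argmax of the lexicographic pair
    key = ov.astype(float) * (lengths.max() + 1) + lengths
    key[ov == 0] = -1
    best = key.argmax(axis=1)
    best_ov = ov[np.arange(len(starts)), best]
    best_len = (isl_end - isl_start)[best]
    best_len = np.where(best_ov > 0, best_len, 0)
    return best_ov, best_len


def assign_cgi(promoters: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    """CpG-island overlap flag and size per promoter.

    ``cgi_overlap`` is true for >= 1 bp overlap; ``cgi_size_bp`` is the
    length of the overlapping island with maximal overlap (ties broken in
    favour of the longer island), 0 when none.
    """
    out = pd.DataFrame({"cgi_overlap": False, "cgi_size_bp": 0},
                       index=promoters.index)
    isl_chroms = set(islands["chrom"].unique())
    missing = set(promoters["chrom"].unique()) - isl_chroms
    if missing and len(islands):
        logger.warning("assign_cgi: no islands on chromosomes %s", sorted(missing))
    for chrom, prom in promoters.groupby("chrom", sort=False):
        isl = islands[islands["chrom"] == chrom]
        if isl.empty:
            continue
        ov, ln = _best_overlap(prom["start"].to_numpy(), prom["end"].to_numpy(),
                               isl["start"].to_numpy(), isl["end"].to_numpy())
        out.loc[prom.index, "cgi_overlap"] = ov > 0
        out.loc[prom.index, "cgi_size_bp"] = ln
    return out


# ---------------------------------------------------------------- GC content

def promoter_gc(promoters: pd.DataFrame, fasta_path) -> pd.DataFrame:
    """GC fraction over each promoter, ambiguous bases excluded from both
    numerator and denominator."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    gc = {}
    for gid, row in promoters.iterrows():
        chrom = row["chrom"]
        if chrom not in fa:
            logger.warning("promoter_gc: chromosome %s missing from FASTA", chrom)
            gc[gid] = np.nan
            continue
        contig = fa[chrom]
        if row["end"] > len(contig):
            logger.warning("promoter_gc: promoter of %s outside sequence bounds", gid)
            gc[gid] = np.nan
            continue
        seq = contig[row["start"]:row["end"]].seq.upper()
        gc[gid] = gc_fraction(seq)
    return pd.DataFrame({"gc_fraction": pd.Series(gc)}).rename_axis("gene_id")


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    g, c = seq.count("G"), seq.count("C")
    denom = g + c + seq.count("A") + seq.count("T")
    return (g + c) / denom if denom else np.nan


# ---------------------------------------------------------------- assembly

def build_feature_table(parts: list[pd.DataFrame], standardize: bool = True,
                        continuous: tuple[str, ...] | None = None
                        ) -> pd.DataFrame:
    """Outer-join per-gene feature parts and optionally z-score continuous columns.

    Standardized copies are added as ``<name>_z``; zero-variance columns are
    flagged in ``table.attrs['constant_columns']`` and left unstandardized.
    Conflicting duplicate columns across parts are rejected.
    """
    table = None
    for part in parts:
        if table is None:
            table = part.copy()
            continue
        shared = table.columns.intersection(part.columns)
        for col in shared:
            both = table[col].dropna().index.intersection(part[col].dropna().index)
            if len(both) and not table.loc[both, col].equals(part.loc[both, col]):
                raise ValueError(f"conflicting values for column {col!r}")
        table = table.combine_first(part) if len(shared) else table.join(
            part, how="outer")
    if table is None:
        raise ValueError("no feature parts given")

    table.attrs["missingness"] = table.isna().mean().to_dict()
    table.attrs["constant_columns"] = []
    if standardize:
        cols = continuous if continuous is not None else [
            c for c in CONTINUOUS_FEATURES if c in table.columns]
        for col in cols:
            vals = pd.to_numeric(table[col], errors="coerce")
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                logger.warning("build_feature_table: column %r constant, "
                               "not standardized", col)
                table.attrs["constant_columns"].append(col)
                continue
            table[f"{col}_z"] = (vals - vals.mean()) / sd
    return table
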