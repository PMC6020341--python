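"""Short CpG islands among early-response genes, and noise versus response.

The central test: rank genes by log2 fold change separately in an early
and a late consecutive-time-point comparison, pair the lists by rank, and
count pairs in which the early gene's CpG island is the smaller.  Under no
association the count is Binomial(n, 1/2); a one-tailed exact binomial
test (equivalently a paired-sample sign test) gives the enrichment
p-value.  A companion analysis relates pre-stimulation expression noise to
the direction of the transcriptional response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 250
DEFAULT_PEAK_FLANK = 500
DEFAULT_BIN_WIDTH = 500


# ---------------------------------------------------------------- filters

def filter_timeseries(counts: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Expression filters for time-course tables.

    ``cage``: keep peaks detected (count > 0) in more than 75% of samples.
    ``rnaseq``: keep genes with mean count > 5 across samples.
    """
    if kind == "cage":
        keep = (counts > 0).mean(axis=1) > 0.75
    elif kind == "rnaseq":
        keep = counts.mean(axis=1) > 5
    else:
        raise ValueError(f"kind must be 'cage' or 'rnaseq', got {kind!r}")
    if keep.sum() == 0:
        raise ValueError("expression filter removed every feature")
    logger.info("filter_timeseries(%s): kept %d of %d features", kind,
                int(keep.sum()), len(counts))
    return counts.loc[keep]


# ---------------------------------------------------------------- CGI at peaks

def assign_cgi_to_peaks(peaks: pd.DataFrame, islands: pd.DataFrame,
                        flank: int = DEFAULT_PEAK_FLANK) -> pd.Series:
    """Island size per peak, using a ``flank``-bp window centred on the peak.

    ``peaks`` has columns chrom, pos (0-based).  An island is assigned when
    it overlaps [pos - flank/2, pos + flank/2); maximal overlap wins, ties
    go to the longer island.  Size 0 when no island.
    """
    from cginoise.annotation import _best_overlap

    half = flank // 2
    win = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": np.maximum(peaks["pos"].to_numpy() - half, 0),
        "end": peaks["pos"].to_numpy() + half,
    }, index=peaks.index)
    out = pd.Series(0, index=peaks.index, name="cgi_size_bp")
    for chrom, w in win.groupby("chrom", sort=False):
        isl = islands[islands["chrom"] == chrom]
        if isl.empty:
            logger.info("assign_cgi_to_peaks: no islands on %s", chrom)
            continue
        ov, ln = _best_overlap(w["start"].to_numpy(), w["end"].to_numpy(),
                               isl["start"].to_numpy(), isl["end"].to_numpy())
        out.loc[w.index] = ln
    return out


# ---------------------------------------------------------------- fold changes

def naive_log2fc(counts: pd.DataFrame, timepoints: list[list[str]],
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Unmoderated log2 fold changes between consecutive time points.

    ``timepoints`` lists the replicate columns of each time point in time
    order; replicates are averaged.  Moderated fold-change tables computed
    elsewhere can be used interchangeably downstream.
    """
    if len(timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    means = [counts[cols].mean(axis=1) for cols in timepoints]
    out = {}
    for t in range(len(means) - 1):
        out[f"fc_{t}v{t + 1}"] = np.log2((means[t + 1] + pseudocount)
                                         / (means[t] + pseudocount))
    return pd.DataFrame(out, index=counts.index)


# ---------------------------------------------------------------- enrichment

@dataclass
class EnrichmentResult:
    n_pairs: int
    n_early_smaller: int
    ties_excluded: int
    p_one_tailed: float
    direction: str                      # "short_early" or "long_early"

    def to_dict(self) -> dict:
        return asdict(self)


def _ranked_top(ts: pd.DataFrame, column: str, top_n: int) -> pd.Index:
    # descending fold change; gene id breaks exact ties deterministically
    s = ts[column].dropna()
    order = sorted(s.index, key=lambda g: (-s.loc[g], str(g)))
    return pd.Index(order[:top_n])


def cgi_size_enrichment(ts: pd.DataFrame, cgi_size: pd.Series,
                        early: str, late: str,
                        top_n: int = DEFAULT_TOP_N) -> EnrichmentResult:
    """Sign test for smaller islands among the top early-response genes.

    Genes with an assigned island (size > 0) are ranked by descending
    log2FC within the early and the late comparison; the r-th early gene
    is paired with the r-th late gene; a success is a strictly smaller
    early island.  Equal-size pairs are excluded, as zero differences are
    in a sign test.  ``p_one_tailed = P(Binomial(n, 1/2) >= successes)``.
    """
    sizes = pd.to_numeric(cgi_size, errors="coerce")
    with_cgi = sizes[sizes > 0].index
    sub = ts.loc[ts.index.intersection(with_cgi)]
    if early not in sub.columns or late not in sub.columns:
        raise ValueError("early/late comparison columns missing")

    avail = min(len(sub[early].dropna()), len(sub[late].dropna()))
    if top_n > avail:
        logger.warning("cgi_size_enrichment: top_n=%d exceeds %d ranked genes; "
                       "using %d", top_n, avail, avail)
        top_n = avail
    early_rank = _ranked_top(sub, early, top_n)
    late_rank = _ranked_top(sub, late, top_n)

    e_sizes = sizes.loc[early_rank].to_numpy()
    l_sizes = sizes.loc[late_rank].to_numpy()
    ties = int((e_sizes == l_sizes).sum())
    successes = int((e_sizes < l_sizes).sum())
    n_pairs = len(e_sizes) - ties
    if n_pairs == 0:
        raise ValueError("all pairs tied; no informative pairs for the sign test")
    p = float(stats.binom.sf(successes - 1, n_pairs, 0.5))
    direction = "short_early" if successes / n_pairs > 0.5 else "long_early"
    return EnrichmentResult(n_pairs=n_pairs, n_early_smaller=successes,
                            ties_excluded=ties, p_one_tailed=p,
                            direction=direction)


# ---------------------------------------------------------------- DE labels

def label_response(unstim: pd.DataFrame, stim: pd.DataFrame,
                   fdr: float = 0.05) -> pd.Series:
    """Per-gene {up, down, nochange} between unstimulated and stimulated cells.

    Library-size-normalized expression is compared with a two-sided
    rank-sum test per gene; Benjamini-Hochberg control at ``fdr``;
    significant genes are split by the sign of the mean log2 fold change.
    """
    if unstim.shape[1] < 20 or stim.shape[1] < 20:
        raise ValueError("need >= 20 cells per group")
    genes = unstim.index.intersection(stim.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between groups")
    a = unstim.loc[genes].to_numpy(dtype=float)
    b = stim.loc[genes].to_numpy(dtype=float)
    # library-size normalization within each group, preserving overall scale
    a = a / (a.sum(axis=0, keepdims=True) / a.sum(axis=0).mean())
    b = b / (b.sum(axis=0, keepdims=True) / b.sum(axis=0).mean())

    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue)
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    lfc = np.log2((b.mean(axis=1) + 1) / (a.mean(axis=1) + 1))
    labels = np.where(~reject, "nochange", np.where(lfc > 0, "up", "down"))
    return pd.Series(labels, index=genes, name="response")


# ---------------------------------------------------------------- noise vs response

def noise_vs_response(noise: pd.DataFrame, labels: pd.Series,
                      cgi_size: pd.Series, bin_width: int = DEFAULT_BIN_WIDTH,
                      use_rcv2: bool = False, min_bin_genes: int = 3
                      ) -> tuple[pd.DataFrame, dict]:
    """Noise by CpG-island size bin and response label, plus one-tailed KS tests.

    Returns a per-(bin, label) summary of mean CV2 (rCV2 when
    ``use_rcv2``) for island genes, with a separate no-island stratum, and
    KS tests of the alternative that up-regulated genes are stochastically
    noisier than down-regulated and than unchanged genes.
    """
    stat = "rcv2" if use_rcv2 else "cv2"
    common = noise.index.intersection(labels.index)
    df = pd.DataFrame({
        "noise": noise.loc[common, stat],
        "label": labels.loc[common],
        "cgi_size": pd.to_numeric(cgi_size.reindex(common), errors="coerce")
        .fillna(0),
    }).dropna(subset=["noise"])

    cgi = df[df["cgi_size"] > 0].copy()
    cgi["bin"] = (cgi["cgi_size"] // bin_width).astype(int)
    rows = []
    for (b, lab), grp in cgi.groupby(["bin", "label"], sort=True):
        mean = grp["noise"].mean() if len(grp) >= min_bin_genes else np.nan
        rows.append({"stratum": "cgi", "bin": b,
                     "bin_start_bp": b * bin_width, "label": lab,
                     "n": len(grp), "mean_noise": mean})
    noncgi = df[df["cgi_size"] == 0]
    for lab, grp in noncgi.groupby("label", sort=True):
        mean = grp["noise"].mean() if len(grp) >= min_bin_genes else np.nan
        rows.append({"stratum": "non_cgi", "bin": -1, "bin_start_bp": -1,
                     "label": lab, "n": len(grp), "mean_noise": mean})
    summary = pd.DataFrame(rows)

    tests = {}
    for stratum, sub in (("cgi", cgi), ("non_cgi", noncgi)):
        up = sub.loc[sub["label"] == "up", "noise"].to_numpy()
        for other in ("down", "nochange"):
            vals = sub.loc[sub["label"] == other, "noise"].to_numpy()
            key = f"{stratum}_up_vs_{other}"
            if len(up) < 3 or len(vals) < 3:
                tests[key] = {"p": np.nan, "n_up": len(up), "n_other": len(vals)}
                continue
            # H1: up stochastically larger, i.e. its CDF lies below
            ks = stats.ks_2samp(up, vals, alternative="less")
            tests[key] = {"p": float(ks.pvalue), "stat": float(ks.statistic),
                          "n_up": len(up), "n_other": len(vals)}
    return summary, tests
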