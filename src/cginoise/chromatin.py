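"""Promoter chromatin state from windowed ChIP/input coverage.

H3K4me3 (activating) and H3K27me3 (repressive) signals are quantified as
log2 fold enrichment of ChIP over matched input in non-overlapping 200-nt
windows, averaged over the windows overlapping each promoter and then over
replicates.  Promoters are classified active / repressed / bivalent / low
by dichotomizing each mark: the H3K4me3 threshold is the local minimum of
a kernel density estimate of the promoter signals (the distribution is
bimodal); the H3K27me3 signal is long-tailed without a density minimum, so
its threshold is the mean over promoters.  A promoter exceeds a mark when
its signal is greater than 1.5x the mark's threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema

from cginoise import feature_screen

logger = logging.getLogger(__name__)

WINDOW = 200
DEFAULT_MULTIPLIER = 1.5


# ---------------------------------------------------------------- enrichment

def fold_enrichment(chip_windows: pd.DataFrame, input_windows: pd.DataFrame,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """log2((chip + pc) / (input + pc)) per window, after normalizing both
    libraries to counts per million.

    Both inputs are window-count frames (chrom, start, end, value) on the
    same non-overlapping 200-nt grid.
    """
    a = chip_windows.reset_index(drop=True)
    b = input_windows.reset_index(drop=True)
    if len(a) != len(b) or not (
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()):
        raise ValueError("chip and input are not on the same window grid")
    chip = a["value"].to_numpy(dtype=float)
    inp = b["value"].to_numpy(dtype=float)
    chip_cpm = chip / max(chip.sum(), 1) * 1e6
    inp_cpm = inp / max(inp.sum(), 1) * 1e6
    out = a[["chrom", "start", "end"]].copy()
    out["value"] = np.log2((chip_cpm + pseudocount) / (inp_cpm + pseudocount))
    return out


# ---------------------------------------------------------------- promoter signal

def promoter_signal(tracks: list[pd.DataFrame],
                    promoters: pd.DataFrame) -> pd.Series:
    """Mean log2 enrichment over windows overlapping each promoter, per
    replicate, then averaged across replicates.  NaN when a promoter
    overlaps no window."""
    per_rep = []
    for track in tracks:
        vals = pd.Series(np.nan, index=promoters.index)
        for chrom, prom in promoters.groupby("chrom", sort=False):
            win = track[track["chrom"] == chrom]
            if win.empty:
                continue
            ws = win["start"].to_numpy()
            we = win["end"].to_numpy()
            wv = win["value"].to_numpy()
            order = np.argsort(ws, kind="stable")
            ws, we, wv = ws[order], we[order], wv[order]
            for gid, p in zip(prom.index, prom[["start", "end"]].to_numpy()):
                lo = np.searchsorted(we, p[0], side="right")
                hi = np.searchsorted(ws, p[1], side="left")
                if hi > lo:
                    vals.loc[gid] = wv[lo:hi].mean()
        missing = vals.isna().sum()
        if missing:
            logger.warning("promoter_signal: %d promoters overlap no window",
                           int(missing))
        per_rep.append(vals)
    return pd.concat(per_rep, axis=1).mean(axis=1)


# ---------------------------------------------------------------- classification

@dataclass
class BivalencyThresholds:
    k4_threshold: float
    k27_threshold: float
    multiplier: float = DEFAULT_MULTIPLIER


def kde_dichotomy_threshold(values: np.ndarray, gridsize: int = 512
                            ) -> tuple[float, dict]:
    """Threshold for a bimodal signal: the lowest interior local minimum of a
    Gaussian KDE (Silverman bandwidth) lying between the two largest modes.

    Raises ``ValueError`` with the grid and density attached when the
    density has no interior minimum (unimodal signal); callers may then
    supply a manual threshold.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.std() == 0:
        raise ValueError("degenerate signal: all values identical; "
                         "supply a manual threshold")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), gridsize)
    dens = kde(grid)
    minima = argrelextrema(dens, np.less)[0]
    maxima = argrelextrema(dens, np.greater)[0]
    diagnostics = {"grid": grid, "density": dens}
    if len(minima) == 0 or len(maxima) < 2:
        raise ValueError("signal density is unimodal (no interior minimum); "
                         "supply a manual threshold override")
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo_mode, hi_mode = grid[top2.min()], grid[top2.max()]
    between = [i for i in minima if lo_mode < grid[i] < hi_mode]
    if not between:
        raise ValueError("no density minimum between the two largest modes; "
                         "supply a manual threshold override")
    best = min(between, key=lambda i: dens[i])
    return float(grid[best]), diagnostics


def classify_bivalency(k4: pd.Series, k27: pd.Series,
                       multiplier: float = DEFAULT_MULTIPLIER,
                       k4_threshold: float | None = None,
                       k27_threshold: float | None = None,
                       min_genes: int = 200) -> pd.DataFrame:
    """Assign {active, repressed, bivalent, low} per gene.

    k4 threshold: KDE density minimum (override with ``k4_threshold``);
    k27 threshold: mean signal over promoters.  A mark is "present" when
    the signal strictly exceeds ``multiplier`` times its threshold; both
    present = bivalent, only k4 = active, only k27 = repressed, neither =
    low.  Genes missing either signal are left unclassified (NaN).
    """
    common = k4.index.intersection(k27.index)
    k4 = k4.loc[common]
    k27 = k27.loc[common]
    defined = k4.notna() & k27.notna()
    if k4_threshold is None and int(defined.sum()) < min_genes:
        raise ValueError(f"need >= {min_genes} genes with defined signals "
                         "for density-based thresholding")
    if k4_threshold is None:
        k4_threshold, _ = kde_dichotomy_threshold(k4[defined].to_numpy())
    if k27_threshold is None:
        k27_threshold = float(k27[defined].mean())
    if k4_threshold <= 0 or k27_threshold <= 0:
        logger.warning("classify_bivalency: non-positive threshold "
                       "(k4=%.3f, k27=%.3f); multiplying by %.2f lowers the bar",
                       k4_threshold, k27_threshold, multiplier)

    k4_on = k4 > multiplier * k4_threshold
    k27_on = k27 > multiplier * k27_threshold
    cls = np.where(k4_on & k27_on, "bivalent",
                   np.where(k4_on, "active",
                            np.where(k27_on, "repressed", "low")))
    out = pd.DataFrame({"k4_signal": k4, "k27_signal": k27,
                        "class": cls}, index=common)
    out.loc[~defined, "class"] = np.nan
    out.attrs["k4_threshold"] = float(k4_threshold)
    out.attrs["k27_threshold"] = float(k27_threshold)
    out.attrs["multiplier"] = float(multiplier)
    return out


# ---------------------------------------------------------------- regression

def category_regression(noise: pd.DataFrame, classes: pd.DataFrame,
                        cgi_size: pd.Series, reference: str = "repressed",
                        response: str = "rcv2") -> feature_screen.RegressionFit:
    """Robust fit of rCV2 on promoter-class indicators (reference =
    repressed) plus standardized CpG-island size."""
    common = noise.index.intersection(classes.index).intersection(cgi_size.index)
    cls = classes.loc[common, "class"]
    present = cls.dropna().unique()
    if reference not in present:
        raise ValueError(f"reference category {reference!r} is empty")
    if len(present) < 2:
        raise ValueError("need at least 2 promoter categories for contrasts")

    X = pd.get_dummies(cls).astype(float)
    X = X.drop(columns=[reference])
    size = pd.to_numeric(cgi_size.loc[common], errors="coerce")
    sd = size.std(ddof=1)
    if np.isfinite(sd) and sd > 0:
        X["cgi_size_z"] = (size - size.mean()) / sd
    y = noise.loc[common, response]
    return feature_screen.robust_fit(y, X, model_kind="multivariate")
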