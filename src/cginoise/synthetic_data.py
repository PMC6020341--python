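"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* negative-binomial single-cell counts whose dispersion (not mean) carries
  planted feature effects, so mean expression and noise can be decoupled;
* promoter/CpG-island annotations with a realistic island size
  distribution (log-normal, truncated at 200 bp);
* bimodal promoter chromatin signals (H3K4me3-like, H3K27me3-like) with
  planted {active, repressed, bivalent, low} classes;
* stimulation time-course log2 fold changes with a planted bias for
  short-island genes to respond in the earliest comparison.

All functions are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PROMOTER_UP = 1000     # bp upstream of the TSS
PROMOTER_DOWN = 500    # bp downstream
CHIP_WINDOW = 200      # nt, non-overlapping windows

CLASSES = ("active", "repressed", "bivalent", "low")


# ================================================================ configs

@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the negative-binomial count generator.

    Mean normalized expression is log-normal (log2 scale); counts for gene i
    in cell j are NB with mean s_j * m_i.  Dispersion follows a two-state
    model: every gene carries the floor ``base_dispersion``; a gene is
    hyper-variable with probability sigmoid(logit(hv_fraction) + eta_i) and
    then adds an excess ``hv_min + Exp(hv_scale)``.  Planted feature
    effects eta_i act on the log-odds of hyper-variability, evaluated on
    standardized feature values, so a protective feature (e.g. a large CpG
    island) lowers the chance that a promoter is noisy rather than pushing
    noise below the sampling floor.
    """

    mean_log2_loc: float = 4.0        # centre of log2 mean expression
    mean_log2_scale: float = 1.5      # spread of log2 mean expression
    base_dispersion: float = 0.3      # centre of the baseline NB dispersion
    base_log_sd: float = 0.4          # gene-to-gene lognormal scatter of the baseline
    hv_fraction: float = 0.25         # baseline probability of hyper-variability
    hv_min: float = 1.0               # minimum dispersion excess of a HV gene
    hv_scale: float = 1.5             # exponential scale of the excess above hv_min
    cell_scale_sd: float = 0.25       # sd of log cell scaling factors
    cgi_fraction: float = 0.6         # fraction of promoters with an island
    cgi_size_log_mean: float = 6.55   # ln bp; median ~700 bp
    cgi_size_log_sd: float = 0.6
    cgi_size_min: int = 200           # islands below this are not annotated
    cgi_size_max: int = 20000
    class_weights: tuple[float, ...] = (0.45, 0.15, 0.15, 0.25)
    early_fraction: float = 0.1
    cgi_size_effect: float = 0.0      # coefficient on z(cgi size) in HV log-odds
    bivalent_effect: float = 0.0      # added to HV log-odds of bivalent genes
    early_effect: float = 0.0         # added to HV log-odds of early responders


@dataclass(frozen=True)
class AnnotationSimConfig:
    """Layout of the synthetic chromosomes and gene models."""

    gene_spacing: int = 50000         # bp between consecutive TSSs
    genes_per_chrom: int = 100
    transcript_log_mean: float = 7.8  # ln bp; median ~2.4 kb
    transcript_log_sd: float = 0.7
    exon_rate: float = 7.0            # n_exons ~ 1 + Poisson(rate)
    gc_background: float = 0.40
    gc_cgi_promoter: float = 0.65
    gc_noncgi_promoter: float = 0.45


@dataclass(frozen=True)
class ChipSimConfig:
    """Bimodal chromatin signal generator.

    k4 signals are drawn per window around a low mode (repressed/low) or a
    high mode (active/bivalent); k27 signals around a background mode with
    an elevated mode for repressed/bivalent promoters.
    """

    k4_low: float = 0.0
    k4_high: float = 4.0
    k4_sd: float = 0.5
    k27_background: float = 0.2
    k27_elevated: float = 3.0
    k27_sd: float = 0.4
    background_sd: float = 0.3        # non-promoter windows


# ================================================================ counts

def _draw_truth(n_genes: int, cfg: CountSimConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    gene_id = [f"gene{i:05d}" for i in range(n_genes)]
    true_mean = 2.0 ** rng.normal(cfg.mean_log2_loc, cfg.mean_log2_scale, n_genes)

    has_cgi = rng.random(n_genes) < cfg.cgi_fraction
    sizes = np.exp(rng.normal(cfg.cgi_size_log_mean, cfg.cgi_size_log_sd, n_genes))
    sizes = np.clip(sizes, cfg.cgi_size_min, cfg.cgi_size_max)
    cgi_size = np.where(has_cgi, np.round(sizes).astype(int), 0)

    w = np.asarray(cfg.class_weights, dtype=float)
    promoter_class = rng.choice(CLASSES, size=n_genes, p=w / w.sum())
    early = rng.random(n_genes) < cfg.early_fraction

    # planted effects shift the hyper-variability log-odds via standardized
    # covariates
    effect = np.zeros(n_genes)
    if cfg.cgi_size_effect != 0.0:
        z = (cgi_size - cgi_size.mean()) / max(cgi_size.std(), 1e-12)
        effect = effect + cfg.cgi_size_effect * z
    if cfg.bivalent_effect != 0.0:
        effect = effect + cfg.bivalent_effect * (promoter_class == "bivalent")
    if cfg.early_effect != 0.0:
        effect = effect + cfg.early_effect * early

    # two-state dispersion: a shared floor plus, for hyper-variable genes,
    # a well-separated right-skewed excess -- the long-tailed residual-noise
    # distribution seen in real data
    if cfg.hv_fraction > 0:
        from scipy.special import expit, logit

        p_hv = expit(logit(cfg.hv_fraction) + effect)
        is_hv = rng.random(n_genes) < p_hv
        excess = np.where(is_hv,
                          cfg.hv_min + rng.exponential(cfg.hv_scale, n_genes),
                          0.0)
    else:
        is_hv = np.zeros(n_genes, dtype=bool)
        excess = np.zeros(n_genes)
    baseline = cfg.base_dispersion * (
        np.exp(rng.normal(0.0, cfg.base_log_sd, n_genes))
        if cfg.base_log_sd > 0 else 1.0)
    true_dispersion = baseline + excess
    return pd.DataFrame({
        "gene_id": gene_id,
        "true_mean": true_mean,
        "true_dispersion": true_dispersion,
        "cgi_size_bp": cgi_size,
        "noise_effect": effect,
        "hyper_variable": is_hv,
        "promoter_class": promoter_class,
        "early_responder": early,
    }).set_index("gene_id")


def simulate_counts(
    n_genes: int,
    n_cells: int,
    cfg: CountSimConfig | None = None,
    seed: int = 0,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an NB gene x cell count matrix with planted dispersion effects.

    Returns ``(counts, truth)`` where truth records per-gene mean,
    dispersion, island size, planted log-dispersion effect, promoter class
    and early-responder flag.  Pass a precomputed ``truth`` to reuse gene
    covariates across generators.
    """
    if n_genes < 2 or n_cells < 10:
        raise ValueError("need n_genes >= 2 and n_cells >= 10")
    cfg = cfg or CountSimConfig()
    if cfg.base_dispersion <= 0:
        raise ValueError("base_dispersion must be positive")
    rng = np.random.default_rng(seed)

    if truth is None:
        truth = _draw_truth(n_genes, cfg, rng)
    elif len(truth) != n_genes:
        raise ValueError("truth table does not match n_genes")

    # cell scaling factors, log-normal with geometric mean 1
    log_s = rng.normal(0.0, cfg.cell_scale_sd, n_cells)
    s = np.exp(log_s - log_s.mean())

    m = truth["true_mean"].to_numpy()[:, None]
    phi = truth["true_dispersion"].to_numpy()[:, None]
    mean = m * s[None, :]
    # NB as gamma-Poisson: var = mean + phi * mean^2
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    counts = rng.poisson(lam).astype(np.int64)

    cells = [f"cell{j:04d}" for j in range(n_cells)]
    cm = pd.DataFrame(counts, index=truth.index, columns=cells)
    truth = truth.copy()
    truth.attrs["cell_scaling"] = pd.Series(s, index=cells)
    return cm, truth


# ================================================================ annotations

def simulate_annotations(
    n_genes: int,
    cfg: AnnotationSimConfig | None = None,
    seed: int = 0,
    truth: pd.DataFrame | None = None,
    count_cfg: CountSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place promoters and CpG islands on synthetic chromosomes.

    Returns ``(genes, islands, structure)``: gene records (chrom, strand,
    interval, TSS), a BED-style island table, and per-gene transcript
    structure features.  Island sizes come from ``truth`` when given
    (``cgi_size_bp``) so annotations agree with the count generator.
    """
    cfg = cfg or AnnotationSimConfig()
    rng = np.random.default_rng(seed)

    if truth is None:
        truth = _draw_truth(n_genes, count_cfg or CountSimConfig(), rng)
    cgi_size = truth["cgi_size_bp"].to_numpy()
    if (cgi_size[cgi_size > 0] + 2 * (PROMOTER_UP + PROMOTER_DOWN) >
            cfg.gene_spacing).any():
        raise ValueError("gene_spacing too small to place islands without "
                         "spilling into neighbouring promoters")

    chrom_len_needed = cfg.genes_per_chrom * cfg.gene_spacing + cfg.gene_spacing
    rows = []
    for i, gid in enumerate(truth.index):
        chrom = f"chrS{i // cfg.genes_per_chrom + 1}"
        slot = i % cfg.genes_per_chrom
        tss = (slot + 1) * cfg.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(np.exp(rng.normal(cfg.transcript_log_mean + 0.8,
                                     cfg.transcript_log_sd)))
        span = min(max(span, 500), cfg.gene_spacing - PROMOTER_UP - PROMOTER_DOWN)
        if strand == "+":
            start, end = tss, tss + span
        else:
            start, end = tss - span + 1, tss + 1
        rows.append((gid, chrom, int(start), int(end), strand, int(tss)))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "tss"]).set_index("gene_id")
    genes.attrs["chrom_length"] = int(chrom_len_needed)

    # one island per CGI-positive gene, centred on its TSS
    isl_rows = []
    for gid, row in genes.iterrows():
        size = int(truth.loc[gid, "cgi_size_bp"])
        if size <= 0:
            continue
        start = max(int(row["tss"]) - size // 2, 0)
        isl_rows.append((row["chrom"], start, start + size, f"CGI_{gid}"))
    islands = pd.DataFrame(isl_rows, columns=["chrom", "start", "end", "name"])
    islands = islands.sort_values(["chrom", "start"]).reset_index(drop=True)

    # transcript structure
    n_exons = 1 + rng.poisson(cfg.exon_rate, n_genes)
    tlen = np.exp(rng.normal(cfg.transcript_log_mean, cfg.transcript_log_sd,
                             n_genes)).round().astype(int)
    structure = pd.DataFrame({
        "transcript_length_bp": tlen,
        "n_exons": n_exons,
        "mean_exon_length_bp": tlen / n_exons,
    }, index=truth.index)
    return genes, islands, structure


def genes_to_gtf_records(genes: pd.DataFrame,
                         structure: pd.DataFrame) -> pd.DataFrame:
    """Expand gene records into GTF-style gene + exon rows (0-based half-open).

    Exons split the transcript length of each gene into ``n_exons`` pieces
    laid out from the TSS, so structure features survive a GTF round trip.
    """
    rows = []
    for gid, g in genes.iterrows():
        rows.append((g["chrom"], "gene", g["start"], g["end"], g["strand"],
                     gid, ""))
        n_ex = int(structure.loc[gid, "n_exons"])
        tlen = int(structure.loc[gid, "transcript_length_bp"])
        sizes = np.full(n_ex, tlen // n_ex, dtype=int)
        sizes[: tlen % n_ex] += 1
        gap = 100
        pos = g["start"] if g["strand"] == "+" else g["end"] - 1
        tid = f"{gid}.t1"
        for k, sz in enumerate(sizes):
            if g["strand"] == "+":
                es, ee = pos, pos + sz
                pos = ee + gap
            else:
                ee, es = pos + 1, pos + 1 - sz
                pos = es - gap - 1
            rows.append((g["chrom"], "exon", int(es), int(ee), g["strand"],
                         gid, tid))
    df = pd.DataFrame(rows, columns=["chrom", "feature", "start", "end",
                                     "strand", "gene_id", "transcript_id"])
    df["source"] = "cginoise"
    return df


def simulate_genome(
    genes: pd.DataFrame,
    islands: pd.DataFrame,
    cfg: AnnotationSimConfig | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Generate chromosome sequences whose promoter GC tracks island status."""
    cfg = cfg or AnnotationSimConfig()
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    cgi_genes = set()
    for name in islands["name"]:
        cgi_genes.add(name.removeprefix("CGI_"))

    chrom_len = genes.attrs.get("chrom_length",
                                int(genes["end"].max()) + 10000)
    seqs: dict[str, np.ndarray] = {}
    for chrom in sorted(genes["chrom"].unique()):
        p = cfg.gc_background
        probs = np.array([(1 - p) / 2, p / 2, p / 2, (1 - p) / 2])
        seqs[chrom] = rng.choice(bases, size=chrom_len, p=probs)
    for gid, g in genes.iterrows():
        tss = int(g["tss"])
        if g["strand"] == "+":
            lo, hi = max(tss - PROMOTER_UP, 0), tss + PROMOTER_DOWN
        else:
            lo, hi = max(tss - PROMOTER_DOWN, 0), tss + PROMOTER_UP
        gc = cfg.gc_cgi_promoter if gid in cgi_genes else cfg.gc_noncgi_promoter
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seqs[g["chrom"]][lo:hi] = rng.choice(bases, size=hi - lo, p=probs)
    return {c: s.tobytes().decode() for c, s in seqs.items()}


# ================================================================ chromatin

def simulate_chip(
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: ChipSimConfig | None = None,
    seed: int = 0,
    n_replicates: int = 2,
) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Windowed log2-enrichment tracks for H3K4me3- and H3K27me3-like marks.

    Promoter windows of {active, bivalent} genes draw from the high k4
    mode; {repressed, bivalent} promoters draw from the elevated k27 mode.
    Returns ``(k4_tracks, k27_tracks)``, one track per replicate, each a
    bedGraph-style frame of non-overlapping 200-nt windows.
    """
    cfg = cfg or ChipSimConfig()
    rng = np.random.default_rng(seed)

    classes = truth["promoter_class"].reindex(genes.index)
    chrom_len = genes.attrs.get("chrom_length", int(genes["end"].max()) + 10000)
    chroms = sorted(genes["chrom"].unique())

    grids = {}
    for chrom in chroms:
        starts = np.arange(0, chrom_len, CHIP_WINDOW)
        grids[chrom] = starts

    k4_tracks, k27_tracks = [], []
    for _rep in range(n_replicates):
        frames4, frames27 = [], []
        for chrom in chroms:
            starts = grids[chrom]
            v4 = rng.normal(cfg.k4_low, cfg.background_sd, len(starts))
            v27 = rng.normal(cfg.k27_background, cfg.background_sd, len(starts))
            frames4.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                         "end": starts + CHIP_WINDOW,
                                         "value": v4}))
            frames27.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                          "end": starts + CHIP_WINDOW,
                                          "value": v27}))
        t4 = pd.concat(frames4, ignore_index=True)
        t27 = pd.concat(frames27, ignore_index=True)
        offset = {chrom: i * len(grids[chrom]) for i, chrom in enumerate(chroms)}
        n_windows = len(grids[chroms[0]])

        v4 = t4["value"].to_numpy()
        v27 = t27["value"].to_numpy()
        for gid, g in genes.iterrows():
            tss = int(g["tss"])
            if g["strand"] == "+":
                lo, hi = max(tss - PROMOTER_UP, 0), tss + PROMOTER_DOWN
            else:
                lo, hi = max(tss - PROMOTER_DOWN, 0), tss + PROMOTER_UP
            # windows are a regular 200-nt grid, so overlap is index arithmetic
            w0 = lo // CHIP_WINDOW
            w1 = min((hi - 1) // CHIP_WINDOW + 1, n_windows)
            base = offset[g["chrom"]]
            nwin = w1 - w0
            cls = classes.loc[gid]
            mu4 = cfg.k4_high if cls in ("active", "bivalent") else cfg.k4_low
            mu27 = (cfg.k27_elevated if cls in ("repressed", "bivalent")
                    else cfg.k27_background)
            v4[base + w0:base + w1] = rng.normal(mu4, cfg.k4_sd, nwin)
            v27[base + w0:base + w1] = rng.normal(mu27, cfg.k27_sd, nwin)
        t4["value"] = v4
        t27["value"] = v27
        k4_tracks.append(t4)
        k27_tracks.append(t27)
    return k4_tracks, k27_tracks


# ================================================================ time series

def simulate_timeseries(
    genes: list[str] | pd.Index,
    cgi_sizes: pd.Series,
    effect: float = 0.0,
    n_timepoints: int = 3,
    seed: int = 0,
    fc_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold changes for consecutive time-point comparisons.

    ``effect > 0`` biases the earliest comparison so that genes with short
    CpG islands are the most up-regulated; later comparisons are unbiased.
    With ``effect = 0`` the early and late rankings are exchangeable.
    """
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints (early and late comparisons)")
    rng = np.random.default_rng(seed)
    genes = pd.Index(genes)
    sizes = cgi_sizes.reindex(genes).fillna(0.0).to_numpy(dtype=float)

    with_cgi = sizes > 0
    shortness = np.zeros(len(genes))
    if with_cgi.any():
        logsz = np.log(sizes[with_cgi])
        z = (logsz - logsz.mean()) / max(logsz.std(), 1e-12)
        shortness[with_cgi] = -z

    out = {}
    for t in range(n_timepoints - 1):
        fc = rng.normal(0.0, fc_sd, len(genes))
        if t == 0:
            fc = fc + effect * shortness
        out[f"fc_{t}v{t + 1}"] = fc
    return pd.DataFrame(out, index=genes.rename("gene_id"))
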