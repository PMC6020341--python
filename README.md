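# cginoise

Gene-expression noise versus promoter architecture, as a tested pipeline.

Isogenic cells expressing the same gene at the same average level can
still differ widely from cell to cell. `cginoise` quantifies that
variability from single-cell RNA-seq count matrices, asks which promoter
features predict it — CpG-island presence and size, promoter GC content,
gene structure, and chromatin state (H3K4me3 / H3K27me3) — and tests
whether the short-island, high-noise promoters are the ones induced
first after cell stimulation. It is aimed at computational biologists
studying transcriptional noise and promoter regulation.

## The statistic

For counts c_ij (gene i, cell j) and deconvolution size factors s_j, let
n_ij = c_ij/s_j and m_i = mean_j n_ij. Noise is the squared coefficient
of variation CV²_i = Var(n_ij)/m_i², whose strong dependence on the mean
is removed by fitting a gamma GLM (identity link)

    E[CV²_i] = a0 + a1 / m_i

and taking the absolute residual, the **residual CV²**:

    rCV²_i = | CV²_i − E[CV²_i] |.

For negative-binomial counts CV² = 1/m + φ, so a1 ≈ 1, a0 tracks the
typical dispersion φ, and rCV² measures a gene's dispersion excess
independent of its expression level. Genomic features X are then
regressed on rCV² with Huber robust linear models (rCV² is long-tailed),
univariately and jointly, testing each coefficient β against 0 with a
t-test. Promoters are classified active / repressed / bivalent / low by
dichotomizing promoter H3K4me3 (kernel-density minimum) and H3K27me3
(mean) enrichment at 1.5× each threshold. Early-response enrichment
pairs the top-250 ranked up-regulated genes of an early and a late
time-point comparison rank-by-rank and applies an exact one-tailed sign
test to "which gene has the smaller CpG island".

Every stage runs on synthetic data with planted ground truth generated
by `cginoise.synthetic_data`, so the whole analysis is testable end to
end without any external download. See `docs/methods.md` for the model
details and caveats.

## Worked example

Generate a demo bundle with planted effects — larger islands lower the
odds that a gene is hyper-variable, bivalent promoters are noisier, and
short-island genes respond earliest — then run the pipeline:

```sh
$ cgi-noise simulate --seed 1 --out demo
{"bivalent_effect": 2.5, "cgi_size_effect": -1.0, "early_effect": 0.0, "timeseries_effect": 1.5}

$ cgi-noise noise --counts demo/counts.tsv --out demo/noise.tsv
a0=0.3533 a1=24.8178 n=600

$ cgi-noise run --input-dir demo --out results
config_hash=6e143c9d4b4779c0 stages=['annotate', 'chromatin', 'noise', 'respond', 'screen']

$ cgi-noise respond --timeseries demo/timeseries.tsv --cgi-sizes demo/truth.tsv --out demo/enr.json
p=0.00024 direction=short_early (153/250)
```

The mean-CV² fit reports a0 = 0.353 — the typical dispersion of the
simulated genes — and a1 = 24.8, which is the expected reciprocal
coefficient after the demo's 25× depth scaling (CV² = 25/M + φ in scaled
count units). The screen output (`results/screen.tsv`) begins:

```
feature          model_kind  beta     se      t      p         n    significant
cgi_size_bp_z    univariate  -0.223   0.035   -6.43  2.7e-10   600  True
gc_fraction_z    univariate  -0.212   0.032   -6.67  5.7e-11   600  True
```

Island size carries a negative coefficient — genes with larger CpG
islands are less noisy, as planted — and GC content, which co-varies
with island presence, follows. The chromatin stage recovers the planted
promoter classes and reports a positive bivalent coefficient (+0.88
versus the repressed reference) in `results/category_regression.tsv`.
The respond stage finds 153 of 250 rank-matched pairs where the early
gene's island is smaller (exact binomial p = 2.4×10⁻⁴, direction
`short_early`): the most strongly induced genes at the first time point
carry shorter islands than those induced later.

Library use without the CLI mirrors the same steps:

```python
from cginoise import noise_stats, feature_screen, synthetic_data

counts, truth = synthetic_data.simulate_counts(2000, 200, seed=0)
table, fit = noise_stats.compute_noise(counts, min_total=0)
fits = feature_screen.univariate_screen(
    table.dropna(subset=["rcv2"]),
    features_table,            # per-gene feature columns, z-scored
    ["cgi_size_bp_z"])
```

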