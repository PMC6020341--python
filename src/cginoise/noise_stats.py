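"""Single-cell count filtering, normalization, and the rCV2 noise statistic.

The measure of gene expression noise is the residual squared coefficient
of variation.  For gene i over m cells with counts c_ij and cell size
factors s_j, let n_ij = c_ij / s_j be the normalized counts and
m_i their per-gene mean (reported on the log2 scale as mu_i = log2 m_i).
In the default (Brennecke) parametrization

    CV2_i = Var(n_ij) / m_i^2,

whose mean dependence is captured by a gamma GLM with identity link,

    E[CV2_i] = a0 + a1 / m_i,

and the noise statistic is the absolute residual

    rCV2_i = | CV2_i - E[CV2_i] |.

For negative-binomial counts with dispersion phi, CV2 = 1/m + phi, so the
fit recovers a1 ~ 1 and a0 ~ phi, and rCV2 isolates each gene's
dispersion excess from its expression level.  A variant that takes the
variance of log2(n + 1) over mu^2 and fits against 1/mu is available as
``cv2_on='log2'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 100_000
DEFAULT_MIN_CELL_FRACTION = 0.01
DEFAULT_MU_FLOOR = 0.1
DEFAULT_POOL_SIZES = (20, 40, 60, 80, 100)


# ---------------------------------------------------------------- filters

def filter_cells(counts: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL,
                 bad_cells: list[str] | None = None) -> pd.DataFrame:
    """Drop cells with total counts strictly below ``min_total`` or listed as bad."""
    totals = counts.sum(axis=0)
    keep = totals >= min_total
    if bad_cells:
        keep &= ~counts.columns.isin(bad_cells)
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("cell filter removed every cell")
    if removed:
        logger.info("filter_cells: removed %d of %d cells", removed, counts.shape[1])
    return counts.loc[:, keep]


def filter_genes(counts: pd.DataFrame,
                 min_cell_fraction: float = DEFAULT_MIN_CELL_FRACTION
                 ) -> pd.DataFrame:
    """Keep genes detected (count > 0) in at least ``min_cell_fraction`` of cells."""
    if not 0 <= min_cell_fraction <= 1:
        raise ValueError("min_cell_fraction must be in [0, 1]")
    frac = (counts > 0).sum(axis=1) / counts.shape[1]
    keep = frac >= min_cell_fraction
    if keep.sum() == 0:
        raise ValueError("gene filter removed every gene")
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_genes: removed %d of %d genes", removed, counts.shape[0])
    return counts.loc[keep]


# ---------------------------------------------------------------- size factors

def _library_size_factors(counts: pd.DataFrame) -> pd.Series:
    totals = counts.sum(axis=0).astype(float)
    s = totals / np.exp(np.log(totals).mean())
    return s


def size_factors(counts: pd.DataFrame, method: str = "deconvolution",
                 pool_sizes: tuple[int, ...] = DEFAULT_POOL_SIZES) -> pd.Series:
    """Per-cell size factors, rescaled to geometric mean 1.

    ``deconvolution`` uses a simplified ring-pool scheme: cells are ordered
    on a ring by library size; each pool of cells is summed and compared to
    the average pseudo-cell, giving one linear equation per pool in the
    per-cell factors, solved by least squares.  Falls back to library-size
    factors below 20 cells or when the solve produces non-positive values.
    """
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("zero-count cell present; filter cells first")
    n = counts.shape[1]
    if method == "library":
        return _library_size_factors(counts)
    if method != "deconvolution":
        raise ValueError(f"unknown size factor method: {method}")
    if n < 20:
        logger.warning("size_factors: %d cells < 20, falling back to library", n)
        return _library_size_factors(counts)

    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    order = np.argsort(lib, kind="stable")       # ring ordered by library size
    ref = x.mean(axis=1)                          # average pseudo-cell
    ok = ref > 0

    ring = x[:, order]
    cs = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(
        np.concatenate([ring, ring], axis=1), axis=1)], axis=1)

    rows, cols, data, targets = [], [], [], []
    row = 0
    for k in sorted({min(k, n) for k in pool_sizes}):
        # pooled sums for every ring window of size k at once
        starts = np.arange(n)
        pooled = cs[:, starts + k] - cs[:, starts]     # genes x n pools
        theta = np.median(pooled[ok] / ref[ok, None], axis=0)
        for start in range(n):
            idx = order[(start + np.arange(k)) % n]
            rows.extend([row] * k)
            cols.extend(idx.tolist())
            data.extend([1.0] * k)
            targets.append(theta[start])
            row += 1
    # low-weight per-cell anchor keeps the system full rank; arithmetic-mean
    # normalization matches the scale the pool equations imply (the pooled
    # ratios against the average pseudo-cell sum to n over all cells)
    lib_sf = lib / lib.mean()
    w = 0.01
    for j in range(n):
        rows.append(row)
        cols.append(j)
        data.append(w)
        targets.append(w * lib_sf[j])
        row += 1

    A = sp.csr_matrix((data, (rows, cols)), shape=(row, n))
    s = spla.lsqr(A, np.asarray(targets), atol=1e-10, btol=1e-10)[0]
    if (s <= 0).any():
        logger.warning("size_factors: non-positive estimates for %d cells, "
                       "falling back to library factors", int((s <= 0).sum()))
        bad = s <= 0
        s[bad] = lib_sf[bad]
    s = s / np.exp(np.log(s).mean())
    return pd.Series(s, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------- moments

def gene_moments(counts: pd.DataFrame, sf: pd.Series, pseudocount: float = 1.0,
                 mu_floor: float = DEFAULT_MU_FLOOR,
                 cv2_on: str = "counts") -> pd.DataFrame:
    """Per-gene mean, variance and CV2 of normalized expression.

    ``mu`` is log2 of the mean normalized count.  With the default
    ``cv2_on='counts'`` (the Brennecke parametrization), ``var_hat`` is the
    sample variance (ddof 1) of the normalized counts c/s and ``cv2`` its
    ratio to the squared mean normalized count; the mean-CV2 fit then uses
    the reciprocal of the mean normalized count.  ``cv2_on='log2'`` instead
    takes the variance of log2(c/s + pseudocount) over mu squared and fits
    against 1/mu; this variant tracks the log-scale expression values but
    leaves a stronger residual mean dependence.  Genes with mu <=
    ``mu_floor`` keep cv2 but are flagged out of the fit, where the
    reciprocal covariate is unbounded.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 cells for a sample variance")
    s = sf.reindex(counts.columns).to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / s[None, :]
    mean_norm = norm.mean(axis=1)
    with np.errstate(divide="ignore"):
        mu = np.log2(mean_norm)
    if cv2_on == "counts":
        var_hat = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = var_hat / mean_norm**2
        fit_x = mean_norm
    elif cv2_on == "log2":
        var_hat = np.log2(norm + pseudocount).var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = var_hat / mu**2
        fit_x = mu
    else:
        raise ValueError("cv2_on must be 'counts' or 'log2'")
    fit_ok = (mu > mu_floor) & np.isfinite(cv2) & (cv2 > 0)
    out = pd.DataFrame({"mean_norm": mean_norm, "mu": mu, "var_hat": var_hat,
                        "cv2": cv2, "fit_x": fit_x, "fit_ok": fit_ok},
                       index=counts.index)
    out.attrs["cv2_on"] = cv2_on
    return out


# ---------------------------------------------------------------- mean-CV2 fit

@dataclass
class MeanCv2Fit:
    a0: float
    a1: float
    deviance: float
    n_genes: int
    n_iter: int
    converged: bool
    negative_expected: bool = False
    se_a0: float = float("nan")
    se_a1: float = float("nan")

    def expected(self, mu: np.ndarray) -> np.ndarray:
        return self.a0 + self.a1 / mu

    def to_dict(self) -> dict:
        return {"a0": self.a0, "a1": self.a1,
                "se_a0": self.se_a0, "se_a1": self.se_a1,
                "deviance": self.deviance,
                "n_genes": self.n_genes, "n_iter": self.n_iter,
                "converged": self.converged,
                "negative_expected": self.negative_expected}


def _gamma_glm(y: np.ndarray, X: np.ndarray, tol: float, maxiter: int):
    start = np.linalg.lstsq(X, y, rcond=None)[0]        # OLS start values
    import warnings
    with warnings.catch_warnings():
        # identity-link gamma is the intended parametrization here
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Gamma(
            link=sm.families.links.Identity()))
        return model.fit(start_params=start, maxiter=maxiter, tol=tol)


def fit_mean_cv2(table: pd.DataFrame, min_genes: int = 50,
                 tol: float = 1e-8, maxiter: int = 100,
                 outlier_sd: float = 3.0) -> MeanCv2Fit:
    """Fit E[CV2] = a0 + a1/x by a gamma GLM with identity link (IRLS).

    The reciprocal covariate x is the ``fit_x`` column of the moments table
    (mean normalized count under the default parametrization).  One
    robustness iteration follows the first pass: genes whose relative
    residual (CV2 - fit)/fit exceeds ``outlier_sd`` robust standard
    deviations (1.4826 * MAD) are dropped and the curve refit, so a handful
    of hyper-variable genes cannot tilt the trend the residuals are taken
    against.  Set ``outlier_sd`` to None or inf to disable.
    """
    fit = table[table["fit_ok"]]
    if len(fit) < min_genes:
        raise ValueError(f"only {len(fit)} genes available for the mean-CV2 "
                         f"fit (need >= {min_genes})")
    y = fit["cv2"].to_numpy()
    x = (fit["fit_x"] if "fit_x" in fit.columns else fit["mu"]).to_numpy()
    X = sm.add_constant(1.0 / x)
    try:
        res = _gamma_glm(y, X, tol, maxiter)
        if outlier_sd is not None and np.isfinite(outlier_sd):
            rel = (y - res.predict(X)) / np.abs(res.predict(X))
            sigma = 1.4826 * np.median(np.abs(rel - np.median(rel)))
            keep = np.abs(rel - np.median(rel)) <= outlier_sd * sigma
            if sigma > 0 and keep.sum() >= min_genes and keep.sum() < len(y):
                res = _gamma_glm(y[keep], X[keep], tol, maxiter)
        a0, a1 = res.params
        se_a0, se_a1 = res.bse
        n_iter = len(getattr(res, "fit_history", {}).get("deviance", [])) or maxiter
        converged = bool(getattr(res, "converged", True))
        deviance = float(res.deviance)
    except Exception:                                    # non-convergent IRLS
        logger.warning("gamma GLM failed; reporting the OLS iterate")
        a0, a1 = np.linalg.lstsq(X, y, rcond=None)[0]
        se_a0 = se_a1 = float("nan")
        n_iter, converged = 0, False
        deviance = float(np.sum((y - X @ [a0, a1]) ** 2))
    expected = a0 + a1 / x
    negative = bool((expected <= 0).any())
    if negative:
        logger.warning("fit_mean_cv2: negative fitted E[CV2] for some genes")
    return MeanCv2Fit(a0=float(a0), a1=float(a1), deviance=deviance,
                      n_genes=len(fit), n_iter=int(n_iter),
                      converged=converged, negative_expected=negative,
                      se_a0=float(se_a0), se_a1=float(se_a1))


def residual_cv2(table: pd.DataFrame, a0: float, a1: float) -> pd.DataFrame:
    """Fill expected_cv2 = a0 + a1/x and rcv2 = |cv2 - expected_cv2|.

    Genes flagged out of the fit get NaN for both.
    """
    out = table.copy()
    x = (out["fit_x"] if "fit_x" in out.columns else out["mu"]).to_numpy()
    with np.errstate(divide="ignore"):
        expected = a0 + a1 / x
    expected = np.where(out["fit_ok"], expected, np.nan)
    out["expected_cv2"] = expected
    out["rcv2"] = np.abs(out["cv2"] - expected)
    return out


def compute_noise(counts: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL,
                  min_cell_fraction: float = DEFAULT_MIN_CELL_FRACTION,
                  sf_method: str = "deconvolution", pseudocount: float = 1.0,
                  mu_floor: float = DEFAULT_MU_FLOOR, cv2_on: str = "counts",
                  ) -> tuple[pd.DataFrame, MeanCv2Fit]:
    """Filter, normalize and compute the full noise table in one call."""
    counts = filter_cells(counts, min_total=min_total)
    counts = filter_genes(counts, min_cell_fraction=min_cell_fraction)
    sf = size_factors(counts, method=sf_method)
    table = gene_moments(counts, sf, pseudocount=pseudocount,
                         mu_floor=mu_floor, cv2_on=cv2_on)
    fit = fit_mean_cv2(table)
    table = residual_cv2(table, fit.a0, fit.a1)
    return table, fit
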