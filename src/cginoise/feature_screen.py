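"""Robust regression of genomic features on expression noise.

rCV2 has a long right tail, so ordinary least squares — whose estimate a
single extreme value can move arbitrarily — is avoided in favour of Huber
M-estimation (tuning constant 1.345, MAD scale), fitted by iteratively
reweighted least squares.  Each feature is tested univariately and jointly
in a multivariate model; coefficients are tested against zero with a
t-test on n - p degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

HUBER_T = 1.345


@dataclass
class RegressionFit:
    model_kind: str                      # "univariate" or "multivariate"
    features: list[str]                  # excludes the intercept
    beta: np.ndarray                     # intercept first
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    n_genes: int
    converged: bool
    weights_mean: float = float("nan")   # mean robust weight (1 = no downweighting)

    def to_frame(self) -> pd.DataFrame:
        names = ["intercept"] + list(self.features)
        return pd.DataFrame({
            "feature": names, "model_kind": self.model_kind,
            "beta": self.beta, "se": self.se, "t": self.t_stat,
            "p": self.p_value, "n": self.n_genes,
            "significant": self.p_value < 0.05,
        })

    def coef(self, feature: str) -> dict:
        i = (["intercept"] + list(self.features)).index(feature)
        return {"beta": self.beta[i], "se": self.se[i],
                "t": self.t_stat[i], "p": self.p_value[i]}


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(len(names)) if i < len(diag)
               and diag[i] < tol]
        raise ValueError(f"design matrix is rank deficient "
                         f"(rank {rank} < {X.shape[1]}); "
                         f"collinear columns include {bad or names}")


def robust_fit(y: pd.Series | np.ndarray, X: pd.DataFrame,
               model_kind: str = "univariate", method: str = "huber",
               tuning: float = HUBER_T, maxiter: int = 200,
               tol: float = 1e-8) -> RegressionFit:
    """Huber (or Tukey bisquare) M-estimation of y on X with intercept.

    Rows with any missing value are dropped (logged).  Standard errors come
    from the M-estimator sandwich covariance; p-values are two-sided
    t-tests on n - p degrees of freedom.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    data = pd.concat([y.rename("__y"), X], axis=1)
    n0 = len(data)
    data = data.dropna()
    if len(data) < n0:
        logger.info("robust_fit: dropped %d rows with missing values",
                    n0 - len(data))
    if len(data) <= X.shape[1] + 2:
        raise ValueError("too few complete observations for the fit")

    names = list(X.columns)
    design = sm.add_constant(data[names].to_numpy(dtype=float),
                             has_constant="add")
    if design.shape[1] == len(names):      # X already contained a constant
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns include {names}")
    _check_rank(design, ["intercept"] + names)

    norms = {"huber": sm.robust.norms.HuberT(t=tuning),
             "bisquare": sm.robust.norms.TukeyBiweight()}
    model = sm.RLM(data["__y"].to_numpy(), design, M=norms[method])
    res = model.fit(scale_est="mad", maxiter=maxiter, tol=tol)

    beta = res.params
    se = res.bse
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = beta / se                    # inf on a perfect fit (se = 0)
    df = len(data) - design.shape[1]
    p = 2 * stats.t.sf(np.abs(t_stat), df)
    n_iter = len(res.fit_history.get("deviance", res.fit_history.get(
        "params", [])))
    converged = n_iter < maxiter
    try:
        weights_mean = float(np.mean(res.weights))
    except AttributeError:             # perfect fit: scale 0, no reweighting
        weights_mean = 1.0
    return RegressionFit(model_kind=model_kind, features=names, beta=beta,
                         se=se, t_stat=t_stat, p_value=p, n_genes=len(data),
                         converged=converged, weights_mean=weights_mean)


def _design_from(noise: pd.DataFrame, features: pd.DataFrame,
                 columns: list[str], response: str) -> tuple[pd.Series, pd.DataFrame]:
    common = noise.index.intersection(features.index)
    y = noise.loc[common, response]
    X = features.loc[common, columns].apply(pd.to_numeric, errors="coerce")
    return y, X


def univariate_screen(noise: pd.DataFrame, features: pd.DataFrame,
                      columns: list[str] | None = None,
                      response: str = "rcv2") -> list[RegressionFit]:
    """One robust fit of rCV2 on each feature column separately."""
    cols = columns or [c for c in features.columns
                       if pd.api.types.is_numeric_dtype(features[c])]
    fits = []
    for col in cols:
        y, X = _design_from(noise, features, [col], response)
        fits.append(robust_fit(y, X, model_kind="univariate"))
    return fits


def multivariate_screen(noise: pd.DataFrame, features: pd.DataFrame,
                        columns: list[str],
                        response: str = "rcv2") -> RegressionFit:
    """Joint robust fit of rCV2 on all selected feature columns."""
    y, X = _design_from(noise, features, list(columns), response)
    return robust_fit(y, X, model_kind="multivariate")


def screens_to_frame(fits: list[RegressionFit]) -> pd.DataFrame:
    """Long-format table (feature, model_kind, beta, se, t, p, n) without intercepts."""
    frames = [f.to_frame() for f in fits]
    out = pd.concat(frames, ignore_index=True)
    return out[out["feature"] != "intercept"].reset_index(drop=True)


def subset_refit(noise: pd.DataFrame, features: pd.DataFrame,
                 exclude_genes: list[str], columns: list[str] | None = None,
                 response: str = "rcv2"
                 ) -> tuple[list[RegressionFit], pd.DataFrame]:
    """Re-run the univariate screens on the complement of an exclusion list.

    Returns the refits and a before/after coefficient comparison table.
    Columns that become constant on the subset are dropped with a log line;
    excluding more than 90% of genes is rejected.
    """
    exclude = set(exclude_genes)
    keep = [g for g in features.index if g not in exclude]
    if len(keep) < 0.1 * len(features):
        raise ValueError("exclusion list removes more than 90% of genes")
    sub_feat = features.loc[keep]
    sub_noise = noise.loc[noise.index.intersection(keep)]

    cols = columns or [c for c in features.columns
                       if pd.api.types.is_numeric_dtype(features[c])]
    usable = []
    for col in cols:
        vals = pd.to_numeric(sub_feat[col], errors="coerce").dropna()
        if vals.nunique() <= 1:
            logger.warning("subset_refit: column %r constant after exclusion, "
                           "dropped", col)
            continue
        usable.append(col)

    before = univariate_screen(noise, features, usable, response)
    after = univariate_screen(sub_noise, sub_feat, usable, response)
    rows = []
    for b, a in zip(before, after):
        rows.append({"feature": b.features[0],
                     "beta_full": b.beta[1], "p_full": b.p_value[1],
                     "beta_subset": a.beta[1], "p_subset": a.p_value[1],
                     "sign_stable": np.sign(b.beta[1]) == np.sign(a.beta[1])})
    return after, pd.DataFrame(rows)
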