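"""Outlier and influence diagnostics for a fitted PPV regression.

Residuals are normalized randomized quantile residuals: for each
observation a uniform draw between the fitted Beta-binomial CDF at
y - 1 and at y is mapped through the standard-Normal quantile, giving
residuals that are approximately N(0, 1) under a well-specified model
despite the discreteness of Y. Leverage (hat values) and Cook's
distances use the Binomial working model under the logit link — exact
Beta-binomial leverage is not available, so these are screening
quantities, not exact influence measures.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .betabinom import BBParams, FittedModel, bb_logpmf, fit

__all__ = [
    "weighted_residuals",
    "hat_values",
    "cooks_distances",
    "diagnostic_table",
    "refit_without",
]

DEFAULT_RESIDUAL_SEED = 20180425


def _cdf_pair(y: int, params: BBParams) -> tuple[float, float]:
    """(F(y-1), F(y)) by one vectorized pmf summation."""
    ks = np.arange(0, y + 1)
    pmf = np.exp(bb_logpmf(ks, params))
    f_y = float(pmf.sum())
    f_ym1 = float(f_y - pmf[-1])
    return min(f_ym1, 1.0), min(f_y, 1.0)


def weighted_residuals(
    model: FittedModel,
    table: pd.DataFrame,
    seed: int = DEFAULT_RESIDUAL_SEED,
) -> np.ndarray:
    """Normalized randomized quantile residuals (approximately N(0,1))."""
    rng = np.random.default_rng(seed)
    mu, sigma = model.predict_musigma(table)
    y = table["y"].to_numpy(dtype=int)
    n = table["n"].to_numpy(dtype=int)
    res = np.empty(len(y))
    for i in range(len(y)):
        lo, hi = _cdf_pair(y[i], BBParams(float(mu[i]), float(sigma[i]), int(n[i])))
        u = rng.uniform(lo, hi) if hi > lo else lo
        res[i] = norm.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))
    return res


def hat_values(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Binomial working-model leverage under the logit link.

    Diagonal of H = W^{1/2} X (X'WX)^{-1} X' W^{1/2} with weights
    w_i = N_i mu_i (1 - mu_i); the diagonal sums to p.
    """
    dm = model.design_for(table)
    mu, _ = model.predict_musigma(table)
    n = table["n"].to_numpy(dtype=float)
    w = n * mu * (1.0 - mu)
    X = dm.X
    M = X.T @ (X * w[:, None])
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular X'WX: cannot compute hat values") from exc
    h = w * np.einsum("ij,jk,ik->i", X, Minv, X)
    return np.clip(h, 0.0, 1.0)


def cooks_distances(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """One-step GLM approximation to Cook's distance.

    D_i = r_i^2 h_i / (p (1 - h_i)^2) with raw Pearson residuals
    r_i = (y_i - N_i mu_i) / sqrt(N_i mu_i (1 - mu_i)) under the
    Binomial working model. h_i = 1 yields +inf with a warning.
    """
    h = hat_values(model, table)
    mu, _ = model.predict_musigma(table)
    y = table["y"].to_numpy(dtype=float)
    n = table["n"].to_numpy(dtype=float)
    w = n * mu * (1.0 - mu)
    r_pearson = (y - n * mu) / np.sqrt(w)
    p = len(model.beta_coef)
    with np.errstate(divide="warn", invalid="ignore"):
        d = r_pearson**2 * h / (p * (1.0 - h) ** 2)
    d[h >= 1.0] = np.inf
    return d


def diagnostic_table(
    model: FittedModel,
    table: pd.DataFrame,
    seed: int = DEFAULT_RESIDUAL_SEED,
    residual_flag: float = 3.0,
    hat_flag: Optional[float] = None,
    cook_flag: Optional[float] = None,
) -> pd.DataFrame:
    """Per-observation residual / leverage / influence with outlier flags.

    Default thresholds: |residual| > 3, hat > 2p/n, Cook > 4/n.
    """
    n_obs = len(table)
    p = len(model.beta_coef)
    hat_flag = 2.0 * p / n_obs if hat_flag is None else hat_flag
    cook_flag = 4.0 / n_obs if cook_flag is None else cook_flag
    res = weighted_residuals(model, table, seed=seed)
    h = hat_values(model, table)
    d = cooks_distances(model, table)
    return pd.DataFrame(
        {
            "residual": res,
            "hat": h,
            "cook": d,
            "flag_residual": np.abs(res) > residual_flag,
            "flag_hat": h > hat_flag,
            "flag_cook": d > cook_flag,
        }
    )


def refit_without(
    model: FittedModel,
    table: pd.DataFrame,
    indices,
) -> tuple[FittedModel, pd.DataFrame]:
    """Refit with the given rows removed and report the coefficient impact.

    Returns the reduced-data model and a table comparing each
    coefficient's estimate before/after, with the shift expressed in
    units of the original standard error.
    """
    reduced = table.reset_index(drop=True).drop(index=list(indices))
    warm = np.concatenate([model.beta_coef, model.gamma_coef])
    refit = fit(reduced, model.spec, start=warm)
    est0 = np.concatenate([model.beta_coef, model.gamma_coef])
    est1 = np.concatenate([refit.beta_coef, refit.gamma_coef])
    se0 = np.concatenate([model.se_beta, model.se_gamma])
    names = model.x_names + model.z_names
    part = ["mean"] * len(model.x_names) + ["dispersion"] * len(model.z_names)
    impact = pd.DataFrame(
        {
            "part": part,
            "term": names,
            "estimate_full": est0,
            "estimate_reduced": est1,
            "shift_in_se": (est1 - est0) / se0,
        }
    )
    return refit, impact
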