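"""Beta-binomial distribution and regression engine.

The count of true positives Y among N calls is modelled Beta-binomially
in the (mu, sigma) parameterization:

    E[Y]   = N * mu
    Var[Y] = N * mu * (1 - mu) * (1 + N*sigma) / (1 + sigma)

with mu the expected PPV and sigma >= 0 the dispersion; sigma = 0 is the
Binomial limit. The bridge to the conventional Beta(alpha, beta) shapes
is alpha = mu/sigma, beta = (1 - mu)/sigma. Covariates enter through a
logit link for mu and a log (or Box-Cox power) link for sigma:

    mu    = exp(x'b) / (1 + exp(x'b))
    sigma = exp(z'g)            (log link)
    sigma = (z'g)^(1/lambda)    (Box-Cox link, z'g > 0)

Models are written (p, q) for the lengths of b and g; z is always a
subset of x. Fitting maximizes the exact joint likelihood by
quasi-Newton with analytic gradients; standard errors come from the
inverse observed information at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit
from scipy.stats import norm

from .design import DesignMatrices, ModelSpec, build_design

__all__ = [
    "BBParams",
    "FittedModel",
    "ConvergenceError",
    "bb_moments",
    "ab_from_musigma",
    "musigma_from_ab",
    "bb_logpmf",
    "bb_cdf",
    "bb_rvs",
    "link_mu",
    "link_sigma",
    "fit",
    "akaike_weight",
]

_SIGMA_BINOM_EPS = 1e-12  # below this, treat as the exact Binomial limit
_ETA_CLIP = 35.0
# sigma below exp(-20) (~2e-9) is numerically Binomial for any realistic
# call-list size; the likelihood is treated as exactly flat beyond the
# clip (zero gradient), keeping objective and gradient consistent
_ZETA_CLIP = (-20.0, 10.0)


def _lgamma_ratio(base, k):
    """ln Gamma(base + k) - ln Gamma(base) for k >= 0, stably.

    The naive difference loses ~half the mantissa once base >> k (the
    two log-gammas agree to many digits), which injects noise of order
    eps * |gammaln(base)| into the likelihood and stalls line searches.
    For base > 1e3 * k, sum ln(1 + j/base) by series instead:
    k*ln(base) + S1/base - S2/(2 base^2) + S3/(3 base^3) with
    S1 = sum j, S2 = sum j^2, S3 = sum j^3 over j < k (error < 1e-8).
    """
    base = np.asarray(base, dtype=float)
    k = np.asarray(k, dtype=float)
    use_series = base > 1e3 * np.maximum(k, 1.0)
    safe_base = np.where(use_series, 1.0, base)  # keep gammaln args modest
    direct = gammaln(safe_base + k) - gammaln(safe_base)
    s1 = k * (k - 1.0) / 2.0
    s2 = (k - 1.0) * k * (2.0 * k - 1.0) / 6.0
    s3 = s1**2
    inv = 1.0 / base  # powers of inv underflow silently for huge base
    series = k * np.log(base) + s1 * inv - s2 * inv**2 / 2.0 + s3 * inv**3 / 3.0
    return np.where(use_series, series, direct)


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge or the design is rank deficient."""


@dataclass(frozen=True)
class BBParams:
    """Beta-binomial parameters in the (mu, sigma) parameterization."""

    mu: float
    sigma: float
    n_trials: int

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie in (0, 1)")
        if self.sigma < 0.0:
            raise ValueError("sigma must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


def bb_moments(params: BBParams) -> tuple[float, float]:
    """Mean and variance of Y: (N*mu, N*mu*(1-mu)*(1+N*sigma)/(1+sigma))."""
    mu, s, n = params.mu, params.sigma, params.n_trials
    return n * mu, n * mu * (1.0 - mu) * (1.0 + n * s) / (1.0 + s)


def ab_from_musigma(mu: float, sigma: float) -> tuple[float, float]:
    """Beta shapes (alpha, beta) = (mu/sigma, (1-mu)/sigma); sigma > 0 only."""
    if sigma <= 0.0:
        raise ValueError("sigma = 0 is the Binomial limit; no Beta shapes exist")
    return mu / sigma, (1.0 - mu) / sigma


def musigma_from_ab(alpha: float, beta_shape: float) -> tuple[float, float]:
    """Inverse bridge: mu = a/(a+b), sigma = 1/(a+b)."""
    s = alpha + beta_shape
    return alpha / s, 1.0 / s


def bb_logpmf(y, params: BBParams) -> np.ndarray | float:
    """Log pmf of the Beta-binomial, stable via log-gamma.

    At sigma = 0 (or numerically indistinguishable from it) returns the
    Binomial log pmf.
    """
    y_arr = np.asarray(y)
    n, mu, s = params.n_trials, params.mu, params.sigma
    if np.any((y_arr < 0) | (y_arr > n)):
        raise ValueError(f"y must lie in [0, {n}]")
    comb = gammaln(n + 1) - gammaln(y_arr + 1) - gammaln(n - y_arr + 1)
    if s < _SIGMA_BINOM_EPS:
        out = comb + y_arr * np.log(mu) + (n - y_arr) * np.log1p(-mu)
    else:
        a, b = ab_from_musigma(mu, s)
        out = (
            comb
            + _lgamma_ratio(a, y_arr)
            + _lgamma_ratio(b, n - y_arr)
            - _lgamma_ratio(a + b, n)
        )
    return out if out.shape else float(out)


def bb_cdf(y, params: BBParams) -> float:
    """P(Y <= y), by summation of the pmf (y < 0 gives 0)."""
    y = int(y)
    if y < 0:
        return 0.0
    if y >= params.n_trials:
        return 1.0
    ks = np.arange(0, y + 1)
    return float(np.exp(bb_logpmf(ks, params)).sum())


def bb_rvs(params: BBParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw Y via the Beta-then-Binomial composition (exact)."""
    if params.sigma < _SIGMA_BINOM_EPS:
        return rng.binomial(params.n_trials, params.mu, size=size)
    a, b = ab_from_musigma(params.mu, params.sigma)
    p = rng.beta(a, b, size=size)
    return rng.binomial(params.n_trials, p)


def link_mu(eta) -> np.ndarray | float:
    """Inverse logit link: mu = exp(eta)/(1+exp(eta))."""
    return expit(eta)


def link_sigma(eta, link: str = "log", boxcox_lambda: Optional[float] = None):
    """Inverse dispersion link: exp(eta) or eta^(1/lambda) (eta > 0)."""
    if link == "log":
        return np.exp(eta)
    if link == "boxcox":
        if boxcox_lambda is None or boxcox_lambda <= 0:
            raise ValueError("boxcox link requires a positive lambda")
        eta_arr = np.asarray(eta, dtype=float)
        if np.any(eta_arr <= 0):
            raise ValueError("boxcox link requires z'gamma > 0")
        out = eta_arr ** (1.0 / boxcox_lambda)
        return out if out.shape else float(out)
    raise ValueError(f"unknown dispersion link {link!r}")


@dataclass
class FittedModel:
    """A fitted (p, q) Beta-binomial regression."""

    spec: ModelSpec
    beta_coef: np.ndarray
    gamma_coef: np.ndarray
    se_beta: np.ndarray
    se_gamma: np.ndarray
    pvalues_beta: np.ndarray
    pvalues_gamma: np.ndarray
    loglik: float
    aic: float
    centering: dict[str, float]
    factor_levels: dict[str, tuple[str, ...]]
    x_names: list[str]
    z_names: list[str]
    x_slices: dict
    z_slices: dict
    converged: bool
    n_obs: int
    covariate_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.beta_coef) + len(self.gamma_coef)

    def design_for(self, table: pd.DataFrame) -> DesignMatrices:
        """Design matrices for new rows on the training scale."""
        return build_design(
            table, self.spec, centering=self.centering, factor_levels=self.factor_levels
        )

    def predict_musigma(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Fitted (mu_i, sigma_i) for each row of a raw covariate table."""
        dm = self.design_for(table)
        mu = link_mu(np.clip(dm.X @ self.beta_coef, -_ETA_CLIP, _ETA_CLIP))
        sigma = link_sigma(
            dm.Z @ self.gamma_coef, self.spec.dispersion_link, self.spec.boxcox_lambda
        )
        return np.asarray(mu), np.asarray(sigma)

    def term_pvalue(self, t, part: str) -> float:
        """Wald p-value for a term; multi-column terms use the max over columns."""
        if part == "mean":
            return float(np.max(self.pvalues_beta[self.x_slices[t]]))
        return float(np.max(self.pvalues_gamma[self.z_slices[t]]))

    def summary(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, z, p) for both parts."""
        rows = []
        for part, names, est, se, pv in (
            ("mean", self.x_names, self.beta_coef, self.se_beta, self.pvalues_beta),
            ("dispersion", self.z_names, self.gamma_coef, self.se_gamma, self.pvalues_gamma),
        ):
            for nm, e, s, p in zip(names, est, se, pv):
                rows.append(
                    {
                        "part": part,
                        "term": nm,
                        "estimate": e,
                        "std_error": s,
                        "z_value": e / s if s > 0 else np.nan,
                        "p_value": p,
                    }
                )
        return pd.DataFrame(rows)


def _nll_grad(theta, y, n, X, Z, link, lam):
    """Joint negative log-likelihood and its analytic gradient."""
    p = X.shape[1]
    beta, gamma = theta[:p], theta[p:]
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)

    if link == "log":
        zeta_raw = Z @ gamma
        zeta = np.clip(zeta_raw, *_ZETA_CLIP)
        sigma = np.exp(zeta)
        inside = (zeta_raw > _ZETA_CLIP[0]) & (zeta_raw < _ZETA_CLIP[1])
        dsig = np.where(inside, sigma, 0.0)  # flat (zero grad) beyond the clip
    else:  # boxcox
        zeta = Z @ gamma
        if np.any(zeta <= 0):  # infeasible region: penalized, not fatal
            bad = np.minimum(zeta, 0.0)
            pen = 1e8 * float((bad**2).sum() + (zeta <= 0).sum())
            gpen = np.concatenate([np.zeros(p), 2e8 * (Z.T @ bad)])
            return pen, gpen
        sigma = zeta ** (1.0 / lam)
        dsig = (1.0 / lam) * zeta ** (1.0 / lam - 1.0)
        floor = np.exp(_ZETA_CLIP[0])
        dsig = np.where(sigma < floor, 0.0, dsig)
        sigma = np.maximum(sigma, floor)

    a = mu / sigma
    b = (1.0 - mu) / sigma
    ll = (
        gammaln(n + 1)
        - gammaln(y + 1)
        - gammaln(n - y + 1)
        + _lgamma_ratio(a, y)
        + _lgamma_ratio(b, n - y)
        - _lgamma_ratio(a + b, n)
    )
    dl_da = digamma(y + a) - digamma(n + a + b) - digamma(a) + digamma(a + b)
    dl_db = digamma(n - y + b) - digamma(n + a + b) - digamma(b) + digamma(a + b)
    dl_dmu = (dl_da - dl_db) / sigma
    dl_dsigma = -(dl_da * mu + dl_db * (1.0 - mu)) / sigma**2
    grad_beta = X.T @ (dl_dmu * mu * (1.0 - mu))
    grad_gamma = Z.T @ (dl_dsigma * dsig)
    return -float(ll.sum()), -np.concatenate([grad_beta, grad_gamma])


def _check_rank(M: np.ndarray, names: Sequence[str], part: str) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1]:
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ConvergenceError(
            f"rank-deficient {part} design; collinear terms: {bad or 'unidentified'}"
        )


def _start_values(y, n, X, Z, link, lam):
    """Two-stage warm start: weighted logistic LS for beta, moments for gamma."""
    prop = np.clip((y + 0.5) / (n + 1.0), 1e-6, 1.0 - 1e-6)
    w = n.astype(float)
    Xw = X * w[:, None]
    beta0, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ logit(prop), rcond=None)
    mu0 = np.clip(expit(np.clip(X @ beta0, -_ETA_CLIP, _ETA_CLIP)), 1e-9, 1 - 1e-9)
    phi = float(np.mean((y - n * mu0) ** 2 / (n * mu0 * (1.0 - mu0))))
    sigma0 = max((phi - 1.0) / max(float(np.median(n)), 1.0), 1e-8)
    gamma0 = np.zeros(Z.shape[1])
    gamma0[0] = np.log(sigma0) if link == "log" else sigma0**lam
    return np.concatenate([beta0, gamma0])


def _newton_polish(fun, theta, f0, max_iter=25, gtol=1e-5):
    """Damped Newton refinement on the analytic gradient.

    L-BFGS-B can quit with a sizeable gradient when the likelihood mixes
    very sharp and very flat directions; Newton steps on the (finite
    difference of the) analytic gradient close the gap. Steps are
    accepted on gradient-norm decrease, which is robust to the tiny
    noise floor of the objective itself.
    """
    f, g = fun(theta)
    best = (theta, f, g)
    for _ in range(max_iter):
        theta, f, g = best
        gn = np.linalg.norm(g)
        if gn < gtol:
            break
        H = _fd_hessian(fun, theta)
        try:
            w_min = float(np.linalg.eigvalsh(H).min())
        except np.linalg.LinAlgError:
            break
        ridge = max(0.0, 1e-8 - w_min) + 1e-10
        try:
            step = np.linalg.solve(H + ridge * np.eye(len(theta)), -g)
        except np.linalg.LinAlgError:
            break
        improved = False
        sc = 1.0
        while sc > 1e-7:
            cand = theta + sc * step
            fc, gc = fun(cand)
            if np.isfinite(fc) and np.linalg.norm(gc) < gn:
                best = (cand, fc, gc)
                improved = True
                break
            sc /= 2.0
        if not improved:
            break
    return best


def _fd_hessian(fun, theta, eps_scale=1e-5):
    """Central finite differences of the analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = eps_scale * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    centering: Optional[Mapping[str, float]] = None,
    start: Optional[np.ndarray] = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    on_nonconvergence: str = "warn",
) -> FittedModel:
    """Maximum-likelihood fit of a (p, q) Beta-binomial regression.

    ``table`` must carry columns y, n and the covariates the spec
    references. ``start`` (a stacked (beta, gamma) vector) warm-starts
    the optimizer, e.g. from a previous fit on nearly the same data.
    Non-convergence is flagged (``converged=False``) and warned about,
    or raised when ``on_nonconvergence='raise'``.
    """
    y = table["y"].to_numpy(dtype=float)
    n = table["n"].to_numpy(dtype=float)
    dm = build_design(table, spec, centering=centering)
    p, q = dm.X.shape[1], dm.Z.shape[1]
    if len(y) < p + q + 1:
        raise ValueError(f"need at least p+q+1={p + q + 1} observations, got {len(y)}")
    _check_rank(dm.X, dm.x_names, "mean")
    _check_rank(dm.Z, dm.z_names, "dispersion")

    lam = spec.boxcox_lambda
    link = spec.dispersion_link

    # optimize on internally standardized columns: second-order terms in
    # depth can be ~1e4 times larger than proportion terms, which wrecks
    # the conditioning of the joint Hessian otherwise
    sx = np.maximum(np.abs(dm.X).max(axis=0), 1e-12)
    sz = np.maximum(np.abs(dm.Z).max(axis=0), 1e-12)
    scale = np.concatenate([sx, sz])
    Xs, Zs = dm.X / sx, dm.Z / sz
    args = (y, n, Xs, Zs, link, lam)

    if start is not None:
        theta0 = np.asarray(start, dtype=float) * scale
    else:
        theta0 = _start_values(y, n, Xs, Zs, link, lam)
        if link == "boxcox":
            # keep the start inside the feasible half-space z'gamma > 0
            theta0[p] = max(theta0[p], 1e-3)

    res = minimize(
        _nll_grad,
        theta0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7, "maxcor": 40},
    )
    theta_s, nll, grad = _newton_polish(
        lambda t: _nll_grad(t, *args), res.x, float(res.fun)
    )
    converged = bool(res.success or np.linalg.norm(grad) < 1e-3 * (1.0 + abs(nll)))
    if not converged:
        msg = f"optimizer did not converge: {res.message}"
        if on_nonconvergence == "raise":
            raise ConvergenceError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    loglik = -float(nll)
    Hs = _fd_hessian(lambda t: _nll_grad(t, *args), theta_s)
    # back to the raw-column scale
    theta = theta_s / scale
    H = Hs * np.outer(scale, scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        var = np.diag(cov).copy()
    var[var <= 0] = np.nan
    se = np.sqrt(var)
    zval = theta / se
    pvals = 2.0 * norm.sf(np.abs(zval))

    ranges = {
        c: (float(table[c].min()), float(table[c].max()))
        for c in table.columns
        if c in {"titv", "hethom", "med_dp", "dp_lt5"}
    }
    return FittedModel(
        spec=spec,
        beta_coef=theta[:p],
        gamma_coef=theta[p:],
        se_beta=se[:p],
        se_gamma=se[p:],
        pvalues_beta=pvals[:p],
        pvalues_gamma=pvals[p:],
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * (p + q),
        centering=dm.centering,
        factor_levels=dm.factor_levels,
        x_names=dm.x_names,
        z_names=dm.z_names,
        x_slices=dm.x_slices,
        z_slices=dm.z_slices,
        converged=converged,
        n_obs=len(y),
        covariate_ranges=ranges,
    )


def akaike_weight(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-D_i/2) / sum_j exp(-D_j/2), D_i = AIC_i - min AIC."""
    a = np.asarray(aics, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two AIC values")
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()
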