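"""Model selection: backward elimination and the dispersion-link scan.

Elimination is p-value driven with an AIC stopping rule: at each step
the removable term with the largest Wald p-value is dropped iff the
refit's AIC decreases (candidates are tried in decreasing p-value
order; the first AIC-improving removal is accepted). Marginality is
respected — a main effect stays while any of its squares or
interactions remain — and the intercept is never removable. The
Box-Cox lambda scan compares AIC across the dispersion-link family
sigma = (z'gamma)^(1/lambda), with lambda = 0 denoting the log link.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .betabinom import ConvergenceError, FittedModel, fit
from .design import ModelSpec, TermDescriptor

__all__ = ["backward_eliminate", "lambda_scan"]


def _removable(spec: ModelSpec, part: str) -> list[TermDescriptor]:
    terms = spec.mean_terms if part == "mean" else spec.dispersion_terms
    out = []
    for t in terms:
        if t.kind == "intercept":
            continue
        if part == "mean" and t in spec.dispersion_terms:
            continue  # dispersion must stay a subset of the mean part
        if t.kind == "main":
            comp = t.components[0]
            if any(u.order == 2 and comp in u.components for u in terms):
                continue  # marginality
        out.append(t)
    return out


def _tie_key(t: TermDescriptor) -> tuple:
    # ties: drop higher-order terms first, then alphabetically by name
    return (-t.order, t.name)


def backward_eliminate(
    table: pd.DataFrame,
    start_spec: ModelSpec,
    part: str = "mean",
) -> tuple[FittedModel, pd.DataFrame]:
    """Backward-eliminate one model part; returns (final model, trace).

    The trace has one row per accepted removal: term, its Wald p-value
    in the model it was removed from, and AIC before/after.
    """
    if part not in {"mean", "dispersion"}:
        raise ValueError("part must be 'mean' or 'dispersion'")
    current = fit(table, start_spec, on_nonconvergence="raise")
    steps = []
    while True:
        candidates = _removable(current.spec, part)
        if not candidates:
            break
        ranked = sorted(
            candidates,
            key=lambda t: (-current.term_pvalue(t, part),) + _tie_key(t),
        )
        accepted = None
        for t in ranked:
            trial_spec = current.spec.drop(t, part)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                trial = fit(table, trial_spec)
            if trial.converged and trial.aic < current.aic:
                accepted = (t, trial)
                break
        if accepted is None:
            break
        t, trial = accepted
        steps.append(
            {
                "part": part,
                "term": t.name,
                "p_value": current.term_pvalue(t, part),
                "aic_before": current.aic,
                "aic_after": trial.aic,
            }
        )
        current = trial
    return current, pd.DataFrame(
        steps, columns=["part", "term", "p_value", "aic_before", "aic_after"]
    )


def lambda_scan(
    table: pd.DataFrame,
    spec: ModelSpec,
    inv_lambdas: Iterable[int] = range(2, 11),
) -> pd.DataFrame:
    """AIC across dispersion links: log (lambda = 0) plus each Box-Cox
    lambda = 1/k for the positive integers ``k`` requested.

    Returns one row per link with columns (lam, inv_lambda, aic,
    converged); the log-link row carries lam = 0. Infeasible or
    non-convergent Box-Cox fits are reported with aic = NaN.
    """
    if spec.q <= 1:
        raise ValueError("lambda scan needs a covariate-dependent dispersion part (q > 1)")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log_fit = fit(table, replace(spec, dispersion_link="log", boxcox_lambda=None))
        rows.append(
            {"lam": 0.0, "inv_lambda": 0, "aic": log_fit.aic, "converged": log_fit.converged}
        )
        any_ok = False
        for k in inv_lambdas:
            k = int(k)
            if k < 1:
                raise ValueError("1/lambda values must be positive integers")
            bc_spec = replace(spec, dispersion_link="boxcox", boxcox_lambda=1.0 / k)
            try:
                m = fit(table, bc_spec)
                rows.append(
                    {"lam": 1.0 / k, "inv_lambda": k, "aic": m.aic, "converged": m.converged}
                )
                any_ok = any_ok or m.converged
            except (ConvergenceError, FloatingPointError, ValueError):
                rows.append(
                    {"lam": 1.0 / k, "inv_lambda": k, "aic": float("nan"), "converged": False}
                )
    if not any_ok:
        warnings.warn(
            "no Box-Cox fit converged; only the log-link row is informative",
            RuntimeWarning,
            stacklevel=2,
        )
    out = pd.DataFrame(rows)
    out.attrs["best_lam"] = float(out.loc[out["aic"].idxmin(), "lam"])
    return out
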