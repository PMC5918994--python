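"""95% prediction intervals for the observed PPV of a call set.

The observed proportion Y/N is approximated as Normal with mean mu-hat
and variance Var[Y]/N^2 taken from the fitted Beta-binomial moments;
the interval is mu-hat +/- z_{0.975} * sd, truncated to [0, 1].
Coefficient-estimation uncertainty is deliberately ignored: the
interval targets the future observed proportion given the fitted
surface, which is adequate when the training set is large. Calibration
is checked by leave-one-out coverage over the training table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .betabinom import FittedModel, fit
from .callset_stats import CallSetStats
from .design import ModelSpec

__all__ = [
    "PredictionInterval",
    "PILengthSummary",
    "predict_interval",
    "loo_intervals",
    "summarize_lengths",
]

Z975 = float(norm.ppf(0.975))  # exact Normal quantile, not 1.96


@dataclass(frozen=True)
class PredictionInterval:
    """Point estimate of PPV with 95% bounds for the observed proportion."""

    point: float
    lower: float
    upper: float

    @property
    def length_pct(self) -> float:
        return 100.0 * (self.upper - self.lower)

    def covers(self, observed: float) -> bool:
        return self.lower <= observed <= self.upper


@dataclass(frozen=True)
class PILengthSummary:
    """Five-number summary of PI lengths (in %) plus observed coverage."""

    min: float
    q1: float
    median: float
    q3: float
    max: float
    coverage_pct: Optional[float] = None
    n_intervals: int = 0


def _stats_to_row(stats: Union[CallSetStats, dict, pd.Series]) -> pd.DataFrame:
    if isinstance(stats, CallSetStats):
        return pd.DataFrame([stats.as_dict()])
    if isinstance(stats, pd.Series):
        return stats.to_frame().T
    return pd.DataFrame([dict(stats)])


def interval_from_musigma(mu: float, sigma: float, n: int) -> PredictionInterval:
    """Closed-form interval given fitted (mu, sigma) and call-list size n."""
    var_prop = mu * (1.0 - mu) * (1.0 + n * sigma) / ((1.0 + sigma) * n)
    half = Z975 * np.sqrt(var_prop)
    return PredictionInterval(
        point=float(mu),
        lower=float(max(mu - half, 0.0)),
        upper=float(min(mu + half, 1.0)),
    )


def predict_interval(
    model: FittedModel,
    stats: Union[CallSetStats, dict, pd.Series],
    n: int,
    *,
    envelope_margin: float = 0.0,
) -> PredictionInterval:
    """95% PI for the observed PPV of a new call set of size ``n``.

    Warns (does not fail) when a quantitative covariate falls outside
    the training range widened by ``envelope_margin`` (a fraction of the
    range) — extrapolation territory.
    """
    if n < 1:
        raise ValueError("n must be positive")
    row = _stats_to_row(stats)
    for cov, (lo, hi) in model.covariate_ranges.items():
        if cov not in row.columns:
            continue
        pad = envelope_margin * (hi - lo)
        v = float(row[cov].iloc[0])
        if v < lo - pad or v > hi + pad:
            warnings.warn(
                f"covariate {cov!r}={v:.4g} outside training range "
                f"[{lo:.4g}, {hi:.4g}]: prediction is an extrapolation",
                UserWarning,
                stacklevel=2,
            )
    mu, sigma = model.predict_musigma(row)
    return interval_from_musigma(float(mu[0]), float(sigma[0]), int(n))


def loo_intervals(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    full_model: Optional[FittedModel] = None,
) -> list[tuple[PredictionInterval, float]]:
    """Leave-one-out prediction intervals over a training table.

    Each row's interval comes from a model fitted on the other rows
    (warm-started at the full-data optimum) and is paired with the
    row's observed proportion y/n. Non-convergent refits are excluded
    with a warning naming their count.
    """
    n_rows = len(table)
    if n_rows < spec.p + spec.q + 2:
        raise ValueError("table too small to leave one out and still fit")
    table = table.reset_index(drop=True)
    if full_model is None:
        full_model = fit(table, spec)
    warm = np.concatenate([full_model.beta_coef, full_model.gamma_coef])

    out: list[tuple[PredictionInterval, float]] = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_rows):
            rest = table.drop(index=i)
            m = fit(rest, spec, start=warm)
            if not m.converged:
                n_failed += 1
                continue
            row = table.iloc[[i]]
            mu, sigma = m.predict_musigma(row)
            pi = interval_from_musigma(float(mu[0]), float(sigma[0]), int(row["n"].iloc[0]))
            out.append((pi, float(row["y"].iloc[0] / row["n"].iloc[0])))
    if n_failed:
        warnings.warn(
            f"{n_failed} leave-one-out refits did not converge and were excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def summarize_lengths(
    intervals: Sequence[tuple[PredictionInterval, float]] | Sequence[PredictionInterval],
    restrict_point_above: Optional[float] = None,
) -> PILengthSummary:
    """Five-number summary (R type-7 quantiles) of PI lengths in percent.

    ``restrict_point_above`` keeps only intervals whose point estimate
    exceeds the threshold (e.g. 0.95 to summarize the high-PPV regime).
    Coverage is reported when observed proportions accompany the
    intervals.
    """
    pis: list[PredictionInterval] = []
    observed: list[float] = []
    for item in intervals:
        if isinstance(item, PredictionInterval):
            pis.append(item)
        else:
            pi, obs = item
            pis.append(pi)
            observed.append(obs)
    if restrict_point_above is not None:
        keep = [i for i, pi in enumerate(pis) if pi.point > restrict_point_above]
        pis = [pis[i] for i in keep]
        observed = [observed[i] for i in keep] if observed else []
    if not pis:
        raise ValueError("no intervals left to summarize (after restriction)")
    lengths = np.array([pi.length_pct for pi in pis])
    q1, med, q3 = np.quantile(lengths, [0.25, 0.5, 0.75])  # linear = R type 7
    coverage = (
        100.0 * float(np.mean([pi.covers(o) for pi, o in zip(pis, observed)]))
        if observed
        else None
    )
    return PILengthSummary(
        min=float(lengths.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(lengths.max()),
        coverage_pct=coverage,
        n_intervals=len(pis),
    )
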