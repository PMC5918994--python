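"""Design-matrix construction for Beta-binomial PPV regression.

Quantitative covariates (titv, hethom, med_dp, dp_lt5) are centered to
their training means before any second-order term is formed; the binary
WES indicator is never centered. Squares and interactions are computed
from the centered values. A model is written (p, q): p mean-part and q
dispersion-part parameters, both parts containing an intercept and the
dispersion terms always a subset of the mean terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QUANTITATIVE_COVARIATES",
    "TermDescriptor",
    "ModelSpec",
    "DesignMatrices",
    "term",
    "center",
    "build_design",
    "named_spec",
    "read_training_table",
    "write_training_table",
]

QUANTITATIVE_COVARIATES = ("titv", "hethom", "med_dp", "dp_lt5")
BINARY_COVARIATES = ("wes_indicator",)
FACTOR_LEVEL_ORDER = {
    "kit_label": ("WGS", "WES-Nextera", "WES-TrueSeq"),
    "caller_label": ("Samtools", "Freebayes"),
}

REQUIRED_COLUMNS = ("y", "n", "titv", "hethom", "med_dp", "dp_lt5", "wes_indicator")


@dataclass(frozen=True)
class TermDescriptor:
    """One model term: intercept, main effect, square or 2-way interaction."""

    kind: str  # {"intercept", "main", "square", "interaction"}
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "intercept" and self.components:
            raise ValueError("intercept takes no components")
        if self.kind == "main" and len(self.components) != 1:
            raise ValueError("main effect takes exactly one component")
        if self.kind == "square":
            if len(self.components) != 1:
                raise ValueError("square takes exactly one component")
            if self.components[0] not in QUANTITATIVE_COVARIATES:
                raise ValueError("square requires a quantitative component")
        if self.kind == "interaction" and (
            len(self.components) != 2 or self.components[0] == self.components[1]
        ):
            raise ValueError("interaction takes two distinct components")

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "1"
        if self.kind == "main":
            return self.components[0]
        if self.kind == "square":
            return f"{self.components[0]}^2"
        return ":".join(self.components)

    @property
    def order(self) -> int:
        return {"intercept": 0, "main": 1, "square": 2, "interaction": 2}[self.kind]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def term(expr: str) -> TermDescriptor:
    """Parse a term string: ``"1"``, ``"titv"``, ``"titv^2"``, ``"wes_indicator:titv"``."""
    expr = expr.strip()
    if expr == "1":
        return TermDescriptor("intercept")
    if expr.endswith("^2"):
        return TermDescriptor("square", (expr[:-2],))
    if ":" in expr:
        a, b = expr.split(":")
        return TermDescriptor("interaction", (a.strip(), b.strip()))
    return TermDescriptor("main", (expr,))


def _terms(exprs: Iterable[str]) -> tuple[TermDescriptor, ...]:
    return tuple(term(e) for e in exprs)


@dataclass(frozen=True)
class ModelSpec:
    """Term lists for the mean (logit link) and dispersion parts.

    ``dispersion_link`` is ``"log"`` (sigma = exp(z'gamma)) or
    ``"boxcox"`` (sigma = (z'gamma)^(1/lambda), requiring z'gamma > 0).
    """

    mean_terms: tuple[TermDescriptor, ...]
    dispersion_terms: tuple[TermDescriptor, ...] = (TermDescriptor("intercept"),)
    dispersion_link: str = "log"
    boxcox_lambda: Optional[float] = None

    def __post_init__(self) -> None:
        if TermDescriptor("intercept") not in self.mean_terms:
            raise ValueError("mean part must include an intercept")
        if TermDescriptor("intercept") not in self.dispersion_terms:
            raise ValueError("dispersion part must include an intercept")
        if not set(self.dispersion_terms) <= set(self.mean_terms):
            raise ValueError("dispersion terms must be a subset of mean terms")
        if self.dispersion_link not in {"log", "boxcox"}:
            raise ValueError("dispersion_link must be 'log' or 'boxcox'")
        if self.dispersion_link == "boxcox" and not (
            self.boxcox_lambda is not None and self.boxcox_lambda > 0
        ):
            raise ValueError("boxcox link requires a positive lambda")

    @property
    def p(self) -> int:
        return len(self.mean_terms)

    @property
    def q(self) -> int:
        return len(self.dispersion_terms)

    def drop(self, t: TermDescriptor, part: str) -> "ModelSpec":
        """Spec with ``t`` removed from the given part (mean removal cascades nowhere)."""
        if part == "mean":
            return replace(self, mean_terms=tuple(x for x in self.mean_terms if x != t))
        if part == "dispersion":
            return replace(
                self, dispersion_terms=tuple(x for x in self.dispersion_terms if x != t)
            )
        raise ValueError("part must be 'mean' or 'dispersion'")


# Mean part of the selected (11, 6) model, in its reported order.
_M11_MEAN = _terms(
    [
        "1",
        "wes_indicator",
        "titv",
        "med_dp",
        "dp_lt5",
        "titv^2",
        "med_dp^2",
        "wes_indicator:titv",
        "wes_indicator:med_dp",
        "wes_indicator:dp_lt5",
        "titv:med_dp",
    ]
)
_M11_DISP = _terms(
    ["1", "wes_indicator", "titv", "dp_lt5", "titv^2", "wes_indicator:titv"]
)

# Global second-order pool: intercept, 5 mains, 4 squares, 4 WES
# interactions, med_dp:hethom, titv:med_dp, titv:dp_lt5 enumerate 17
# terms; the 18th slot defaults to titv:hethom (config-overridable).
_GLOBAL17 = _terms(
    [
        "1",
        "wes_indicator",
        "titv",
        "hethom",
        "med_dp",
        "dp_lt5",
        "titv^2",
        "hethom^2",
        "med_dp^2",
        "dp_lt5^2",
        "wes_indicator:titv",
        "wes_indicator:hethom",
        "wes_indicator:med_dp",
        "wes_indicator:dp_lt5",
        "med_dp:hethom",
        "titv:med_dp",
        "titv:dp_lt5",
    ]
)
_GLOBAL18 = _GLOBAL17 + (term("titv:hethom"),)

# 15-term mean model retaining the Het/Hom structure: the global pool
# minus the purely exploratory curvature/interaction terms.
_M15_MEAN = tuple(
    t for t in _GLOBAL18 if t not in {term("hethom^2"), term("dp_lt5^2"), term("titv:hethom")}
)

_NAMED: dict[str, ModelSpec] = {
    "m11_6": ModelSpec(_M11_MEAN, _M11_DISP),
    "m11_1": ModelSpec(_M11_MEAN),
    "m15_1": ModelSpec(_M15_MEAN),
    "global_mean_18": ModelSpec(_GLOBAL18),
    "global_mean_17": ModelSpec(_GLOBAL17),
}


def named_spec(name: str, extra_18th_term: Optional[str] = None) -> ModelSpec:
    """Return a named model specification.

    ``m11_6``: the selected model with covariate-dependent dispersion;
    ``m11_1``/``m15_1``: intercept-only dispersion; ``global_mean_18``:
    the full second-order starting pool (``extra_18th_term`` overrides
    its default 18th term, ``titv:hethom``).
    """
    if name not in _NAMED:
        raise KeyError(f"unknown spec {name!r}; known: {sorted(_NAMED)}")
    spec = _NAMED[name]
    if extra_18th_term is not None:
        if name != "global_mean_18":
            raise ValueError("extra_18th_term applies only to global_mean_18")
        spec = ModelSpec(_GLOBAL17 + (term(extra_18th_term),))
    return spec


def center(
    table: pd.DataFrame,
    covariates: Sequence[str] = QUANTITATIVE_COVARIATES,
    constants: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Center quantitative covariates to the (stored) training means.

    Pass ``constants`` to re-apply a training centering to new data; the
    WES indicator and factor labels are left untouched.
    """
    out = table.copy()
    used: dict[str, float] = {}
    for cov in covariates:
        if cov not in out.columns:
            raise KeyError(f"covariate {cov!r} absent from table")
        c = float(constants[cov]) if constants is not None else float(out[cov].mean())
        out[cov] = out[cov] - c
        used[cov] = c
    return out, used


@dataclass
class DesignMatrices:
    """Mean- and dispersion-part design matrices plus bookkeeping."""

    X: np.ndarray
    Z: np.ndarray
    x_names: list[str]
    z_names: list[str]
    x_slices: dict[TermDescriptor, list[int]]
    z_slices: dict[TermDescriptor, list[int]]
    centering: dict[str, float]
    factor_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _term_columns(
    centered: pd.DataFrame,
    t: TermDescriptor,
    factor_levels: dict[str, tuple[str, ...]],
) -> tuple[list[str], list[np.ndarray]]:
    n = len(centered)

    def component_cols(cov: str) -> tuple[list[str], list[np.ndarray]]:
        if cov in factor_levels:  # treatment coding, first level = reference
            levels = factor_levels[cov]
            names, cols = [], []
            for lev in levels[1:]:
                names.append(f"{cov}[{lev}]")
                cols.append((centered[cov].to_numpy() == lev).astype(float))
            return names, cols
        if cov not in centered.columns:
            raise KeyError(f"term {t.name!r} references missing covariate {cov!r}")
        return [cov], [centered[cov].to_numpy(dtype=float)]

    if t.kind == "intercept":
        return ["(Intercept)"], [np.ones(n)]
    if t.kind == "main":
        return component_cols(t.components[0])
    if t.kind == "square":
        names, cols = component_cols(t.components[0])
        return [f"{names[0]}^2"], [cols[0] ** 2]
    names_a, cols_a = component_cols(t.components[0])
    names_b, cols_b = component_cols(t.components[1])
    names, cols = [], []
    for na, ca in zip(names_a, cols_a):
        for nb, cb in zip(names_b, cols_b):
            names.append(f"{na}:{nb}")
            cols.append(ca * cb)
    return names, cols


def build_design(
    table: pd.DataFrame,
    spec: ModelSpec,
    centering: Optional[Mapping[str, float]] = None,
    factor_levels: Optional[Mapping[str, tuple[str, ...]]] = None,
) -> DesignMatrices:
    """Build X (mean) and Z (dispersion) matrices from a raw table.

    Centering constants and factor level orders are computed from the
    table when not supplied, and returned for reuse on new data so that
    prediction sees exactly the training-scale covariates.
    """
    needed = {c for t in spec.mean_terms for c in t.components}
    quant = [c for c in QUANTITATIVE_COVARIATES if c in needed or c in table.columns]
    centered, consts = center(table, quant, constants=centering)

    levels: dict[str, tuple[str, ...]] = dict(factor_levels or {})
    for cov in needed:
        if cov in QUANTITATIVE_COVARIATES or cov in BINARY_COVARIATES:
            continue
        if cov not in table.columns:
            raise KeyError(f"model term references missing covariate {cov!r}")
        if cov not in levels:
            seen = list(pd.unique(table[cov].astype(str)))
            canonical = FACTOR_LEVEL_ORDER.get(cov)
            if canonical and set(seen) <= set(canonical):
                levels[cov] = tuple(l for l in canonical if l in seen)
            else:
                levels[cov] = tuple(sorted(seen))

    def build_part(terms: Sequence[TermDescriptor]):
        names: list[str] = []
        cols: list[np.ndarray] = []
        slices: dict[TermDescriptor, list[int]] = {}
        for t in terms:
            tn, tc = _term_columns(centered, t, levels)
            slices[t] = list(range(len(names), len(names) + len(tn)))
            names.extend(tn)
            cols.extend(tc)
        return np.column_stack(cols), names, slices

    X, x_names, x_slices = build_part(spec.mean_terms)
    Z, z_names, z_slices = build_part(spec.dispersion_terms)
    return DesignMatrices(X, Z, x_names, z_names, x_slices, z_slices, consts, levels)


def read_training_table(
    source,
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a delimited training table (one call set per row).

    ``column_map`` renames source columns onto the required names
    (y, n, titv, hethom, med_dp, dp_lt5, wes_indicator), which lets the
    published raw/processed input tables be read directly.
    """
    df = pd.read_csv(source, sep=sep, engine="python")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"training table missing required columns: {missing}")
    if ((df["y"] < 0) | (df["y"] > df["n"])).any():
        raise ValueError("training table violates 0 <= y <= n")
    if (df["n"] < 1).any():
        raise ValueError("training table requires n >= 1")
    return df


def write_training_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)
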