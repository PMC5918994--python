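"""Call-set summary statistics used as PPV predictors.

A call set is characterized by its size N, transition/transversion ratio
(Ti/Tv), heterozygous/homozygous-alt ratio (Het/Hom), median depth
(MedDp), the fraction of calls with depth below five (DpLt5), and a
binary WES indicator. High-quality human call sets have Ti/Tv near 2.0
genome-wide and near 3.0 in exonic targets; an excess of false positives
depresses Ti/Tv toward the random-substitution value of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional

from .vcf_io import VariantRecord

__all__ = [
    "CallSetStats",
    "UndefinedStatisticError",
    "classify_substitution",
    "compute_stats",
]

_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})
_BASES = frozenset("ACGT")


class UndefinedStatisticError(ValueError):
    """A ratio statistic has a zero denominator (names the statistic)."""


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as transition or transversion.

    Transitions are the purine-purine (A<->G) and pyrimidine-pyrimidine
    (C<->T) exchanges; the remaining 8 of the 12 ordered substitutions
    are transversions.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"


@dataclass(frozen=True)
class CallSetStats:
    """Per-call-set predictor vector (one row of a training table)."""

    n_calls: int
    titv: float
    hethom: float
    med_dp: float
    dp_lt5: float
    wes_indicator: int
    kit_label: Optional[str] = None
    caller_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_calls < 1:
            raise ValueError("n_calls must be positive")
        if not 0.0 <= self.dp_lt5 <= 1.0:
            raise ValueError("dp_lt5 must lie in [0, 1]")
        if self.wes_indicator not in (0, 1):
            raise ValueError("wes_indicator must be 0 or 1")

    def as_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "titv": self.titv,
            "hethom": self.hethom,
            "med_dp": self.med_dp,
            "dp_lt5": self.dp_lt5,
            "wes_indicator": self.wes_indicator,
            "kit_label": self.kit_label,
            "caller_label": self.caller_label,
        }


def compute_stats(
    records: Iterable[VariantRecord],
    wes_indicator: int,
    kit_label: Optional[str] = None,
    caller_label: Optional[str] = None,
    strict: bool = True,
) -> CallSetStats:
    """Summarize a filtered stream of non-reference SNV calls.

    Only het and hom_alt records are counted: N, Ti/Tv, Het/Hom, MedDp
    and DpLt5 are all computed on the same record set, so N here equals
    the TP + FP universe a validation run partitions. With
    ``strict=False`` an undefined ratio (no transversions / no hom_alt)
    becomes NaN instead of an error — useful for tiny toy sets.
    """
    n = n_ti = n_tv = n_het = n_hom = n_lt5 = 0
    depths: list[int] = []
    for rec in records:
        if rec.genotype not in {"het", "hom_alt"}:
            continue
        n += 1
        if classify_substitution(rec.ref, rec.alt) == "transition":
            n_ti += 1
        else:
            n_tv += 1
        if rec.genotype == "het":
            n_het += 1
        else:
            n_hom += 1
        depths.append(rec.depth)
        if rec.depth < 5:
            n_lt5 += 1
    if n == 0:
        raise UndefinedStatisticError("empty call set: no het/hom_alt records")
    if strict and n_tv == 0:
        raise UndefinedStatisticError("titv undefined: zero transversions")
    if strict and n_hom == 0:
        raise UndefinedStatisticError("hethom undefined: zero hom_alt calls")
    return CallSetStats(
        n_calls=n,
        titv=n_ti / n_tv if n_tv else float("nan"),
        hethom=n_het / n_hom if n_hom else float("nan"),
        med_dp=float(median(depths)),
        dp_lt5=n_lt5 / n,
        wes_indicator=int(wes_indicator),
        kit_label=kit_label,
        caller_label=caller_label,
    )
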