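"""Gold-standard validation of an SNV call set.

Compares a candidate call list against a truth set inside confident
regions and counts TP/FP/FN, yielding the observed PPV = TP/(TP+FP) and
sensitivity = TP/(TP+FN). One validation run produces one training
observation (Y = TP, N = TP + FP, plus the call-set statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .callset_stats import CallSetStats, compute_stats
from .vcf_io import Region, VariantRecord, _index_contains, _index_regions, normalize_contig

__all__ = ["ValidationReport", "match_variants", "ppv_from_counts"]


@dataclass(frozen=True)
class ValidationReport:
    """TP/FP/FN counts and derived rates for one call set.

    ``specificity`` is None: true negatives are ill-defined for variant
    calling without an agreed site universe.
    """

    tp: int
    fp: int
    fn: int
    ppv: float
    sensitivity: float
    stats: CallSetStats
    specificity: None = None


def ppv_from_counts(tp: int, fp: int) -> float:
    """Observed PPV (precision) from explicit TP/FP counts."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("PPV undefined: tp + fp = 0")
    return tp / (tp + fp)


def _key(rec: VariantRecord, genotype_aware: bool) -> tuple:
    base = (normalize_contig(rec.contig), rec.pos, rec.ref, rec.alt)
    return base + (rec.genotype,) if genotype_aware else base


def match_variants(
    calls: Iterable[VariantRecord],
    truth: Iterable[VariantRecord],
    confident: Sequence[Region],
    *,
    genotype_aware: bool = True,
    wes_indicator: int = 0,
    kit_label: Optional[str] = None,
    caller_label: Optional[str] = None,
) -> ValidationReport:
    """Validate ``calls`` against ``truth`` within confident regions.

    Both sets are restricted to the confident regions first. A call is a
    TP iff a truth record matches on (contig, pos, ref, alt) and — under
    the default genotype-aware policy — on genotype class as well; a
    genotype mismatch at a shared site therefore counts one FP and one
    FN. Duplicate records (e.g. after multi-allelic decomposition)
    count once.
    """
    confident = list(confident)
    if not confident:
        raise ValueError("empty confident-region set: nothing is comparable")

    call_recs = _restrict(calls, confident)
    truth_recs = _restrict(truth, confident)

    call_keys = {_key(r, genotype_aware): r for r in call_recs}
    truth_keys = {_key(r, genotype_aware) for r in truth_recs}

    tp = sum(1 for k in call_keys if k in truth_keys)
    fp = len(call_keys) - tp
    fn = len(truth_keys) - tp

    stats = compute_stats(
        call_keys.values(),
        wes_indicator=wes_indicator,
        kit_label=kit_label,
        caller_label=caller_label,
        strict=False,  # tiny toy sets may lack transversions or hom_alt calls
    )
    return ValidationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        ppv=ppv_from_counts(tp, fp),
        sensitivity=tp / (tp + fn) if tp + fn else 1.0,
        stats=stats,
    )


def _restrict(records: Iterable[VariantRecord], confident: Sequence[Region]) -> list[VariantRecord]:
    index = _index_regions(confident)
    return [
        r for r in records if _index_contains(index, normalize_contig(r.contig), r.pos, True)
    ]
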