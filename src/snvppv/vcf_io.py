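"""Read SNV call lists from VCF and target regions from BED.

Produces a clean stream of biallelic SNV records after applying the
QUAL / DP / contig / region / genotype filters that define a call list.
VCF positions are 1-based; BED intervals are 0-based half-open, so a
record at position ``p`` falls inside ``Region(start, end)`` iff
``start <= p - 1 < end``.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from cyvcf2 import VCF

__all__ = [
    "VariantRecord",
    "Region",
    "FilterSpec",
    "VcfParseError",
    "BedFormatError",
    "ContigMismatchError",
    "read_snvs",
    "read_regions",
    "regions_contain",
    "normalize_contig",
    "DEFAULT_CONTIGS",
]

_BASES = frozenset("ACGT")

#: Human autosomes plus X: mitochondria, Y and unplaced contigs carry
#: abnormal Ti/Tv and are excluded from the modelled call universe.
DEFAULT_CONTIGS = frozenset(str(c) for c in range(1, 23)) | {"X"}


class VcfParseError(ValueError):
    """A VCF record could not be parsed into an SNV call."""


class BedFormatError(ValueError):
    """A BED line violates the 3+ column 0-based half-open contract."""


class ContigMismatchError(ValueError):
    """VCF and BED use incompatible contig naming (chr-prefix mismatch)."""


def normalize_contig(contig: str) -> str:
    """Strip a leading ``chr`` so ``chr1`` and ``1`` compare equal."""
    return contig[3:] if contig.lower().startswith("chr") else contig


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV call.

    ``pos`` is 1-based. ``genotype`` is the diploid class with respect to
    the single alt allele: ``het``, ``hom_alt``, ``hom_ref`` or ``missing``.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str
    qual: float = 0.0
    depth: int = 0

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("VariantRecord is SNV-only: ref/alt must be single bases")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.genotype not in {"het", "hom_alt", "hom_ref", "missing"}:
            raise ValueError(f"unknown genotype class {self.genotype!r}")


@dataclass(frozen=True, order=True)
class Region:
    """A 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region: start={self.start} >= end={self.end}")


@dataclass
class FilterSpec:
    """Filters defining a call list.

    ``min_qual``/``min_dp`` are inclusive lower thresholds; ``contigs`` is
    a set of allowed contig names (chr-prefix insensitive); ``regions``
    restricts to merged BED intervals; ``require_nonref`` keeps only het
    and hom_alt genotypes.
    """

    min_qual: Optional[float] = None
    min_dp: Optional[int] = None
    contigs: Optional[frozenset[str]] = None
    regions: Optional[Sequence[Region]] = None
    require_nonref: bool = False
    normalize_chr: bool = True

    _region_index: Optional[Mapping[str, tuple[list[int], list[int]]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.contigs is not None:
            self.contigs = frozenset(normalize_contig(c) for c in self.contigs)
        if self.regions is not None:
            self._region_index = _index_regions(self.regions)

    def passes(self, rec: VariantRecord) -> bool:
        if self.min_qual is not None and rec.qual < self.min_qual:
            return False
        if self.min_dp is not None and rec.depth < self.min_dp:
            return False
        contig = normalize_contig(rec.contig)
        if self.contigs is not None and contig not in self.contigs:
            return False
        if self._region_index is not None:
            if not _index_contains(self._region_index, contig, rec.pos, self.normalize_chr):
                return False
        if self.require_nonref and rec.genotype not in {"het", "hom_alt"}:
            return False
        return True


def _index_regions(regions: Iterable[Region]) -> dict[str, tuple[list[int], list[int]]]:
    merged = merge_regions(regions)
    index: dict[str, tuple[list[int], list[int]]] = {}
    for reg in merged:
        starts, ends = index.setdefault(normalize_contig(reg.contig), ([], []))
        starts.append(reg.start)
        ends.append(reg.end)
    return index


def _index_contains(
    index: Mapping[str, tuple[list[int], list[int]]],
    contig: str,
    pos: int,
    normalize: bool,
) -> bool:
    if contig not in index:
        if not normalize and any(normalize_contig(c) == contig for c in index):
            raise ContigMismatchError(
                f"contig {contig!r} matches a BED contig only after chr-prefix "
                "normalization; enable normalize_chr or harmonize names"
            )
        return False
    starts, ends = index[contig]
    i = bisect_right(starts, pos - 1) - 1  # 0-based coordinate of the call
    return i >= 0 and pos - 1 < ends[i]


def merge_regions(regions: Iterable[Region]) -> list[Region]:
    """Sort and merge overlapping/adjacent intervals per contig."""
    out: list[Region] = []
    for reg in sorted(regions, key=lambda r: (normalize_contig(r.contig), r.start, r.end)):
        if (
            out
            and normalize_contig(out[-1].contig) == normalize_contig(reg.contig)
            and reg.start <= out[-1].end
        ):
            if reg.end > out[-1].end:
                out[-1] = Region(out[-1].contig, out[-1].start, reg.end)
        else:
            out.append(reg)
    return out


def regions_contain(regions: Sequence[Region], contig: str, pos: int) -> bool:
    """True iff the 1-based position lies in one of the intervals."""
    index = _index_regions(regions)
    return _index_contains(index, normalize_contig(contig), pos, True)


def read_regions(bed_source: str | os.PathLike) -> list[Region]:
    """Read a 3+ column BED file into merged, sorted, disjoint regions."""
    regions: list[Region] = []
    with open(bed_source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedFormatError(f"line {lineno}: fewer than 3 BED columns")
            contig, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(
                    f"line {lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
                ) from exc
            if start >= end:
                raise BedFormatError(f"line {lineno}: start {start} >= end {end}")
            regions.append(Region(contig, start, end))
    return merge_regions(regions)


def _genotype_class(alleles: Sequence[int], alt_index: int) -> str:
    """Diploid genotype class with respect to one alt allele (1-based index)."""
    if any(a < 0 for a in alleles) or len(alleles) == 0:
        return "missing"
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt >= 2:
        return "hom_alt"
    if n_alt == 1:
        return "het"
    return "hom_ref"


def read_snvs(
    vcf_source: str | os.PathLike,
    filters: Optional[FilterSpec] = None,
) -> Iterator[VariantRecord]:
    """Yield filtered biallelic SNV records from a VCF file.

    Multi-allelic sites are decomposed into one record per alt allele;
    non-SNV alts (indels, symbolic alleles) are dropped individually.
    Depth comes from the first sample's FORMAT DP, falling back to INFO
    DP, then 0; a missing QUAL is treated as 0.
    """
    if filters is None:
        filters = FilterSpec()
    vcf = VCF(str(vcf_source))
    n_samples = len(vcf.samples)
    for ordinal, var in enumerate(vcf, start=1):
        try:
            ref = var.REF.upper()
            if len(ref) != 1 or ref not in _BASES:
                continue
            depth = _record_depth(var, n_samples)
            qual = float(var.QUAL) if var.QUAL is not None else 0.0
            alleles = list(var.genotypes[0][:-1]) if n_samples else []
            for alt_index, alt in enumerate(var.ALT, start=1):
                alt = alt.upper()
                if len(alt) != 1 or alt not in _BASES:
                    continue
                rec = VariantRecord(
                    contig=var.CHROM,
                    pos=var.POS,
                    ref=ref,
                    alt=alt,
                    genotype=_genotype_class(alleles, alt_index) if n_samples else "missing",
                    qual=qual,
                    depth=depth,
                )
                if filters.passes(rec):
                    yield rec
        except ContigMismatchError:
            raise
        except Exception as exc:  # malformed record content
            raise VcfParseError(f"cannot parse VCF record #{ordinal}: {exc}") from exc
    vcf.close()


def _record_depth(var, n_samples: int) -> int:
    if n_samples:
        try:
            dp = var.format("DP")
            if dp is not None:
                val = int(dp[0][0])
                if val >= 0:
                    return val
        except (KeyError, TypeError, ValueError):
            pass
    info_dp = var.INFO.get("DP")
    if info_dp is not None:
        try:
            return max(int(info_dp), 0)
        except (TypeError, ValueError):
            return 0
    return 0
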