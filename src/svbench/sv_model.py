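"""Canonical SV data model, coordinate conventions, and interval arithmetic.

Coordinates are 0-based, half-open throughout the package; VCF input/output
converts from/to 1-based at the boundary (see :mod:`svbench.io_calls`).

The model covers deletions (DEL), duplications (DUP), insertions (INS) and
inversions (INV). Translocations/breakends are deliberately unsupported:
normalization either drops them or reassigns them, never accepts them.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Optional

_id_counter = itertools.count()


class SVType(enum.Enum):
    """Closed enumeration of supported structural-variant types."""

    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SVModelError(ValueError):
    """Contract violation in the SV data model (malformed record or misuse)."""


#: Size-range bins used for stratified evaluation. Deletions are split into
#: four ranges and duplications into three; insertions and inversions are
#: evaluated as single categories. Bounds are lower-inclusive/upper-exclusive
#: except the final 1 Mb bound, which is inclusive so variants sized exactly
#: 1 Mb remain binned.
@dataclass(frozen=True)
class SizeClass:
    label: str
    lower: int
    upper: int

    def contains(self, length: int, *, final: bool = False) -> bool:
        if final:
            return self.lower <= length <= self.upper
        return self.lower <= length < self.upper


DEL_BINS = (
    SizeClass("DEL-SS", 50, 100),
    SizeClass("DEL-S", 100, 1_000),
    SizeClass("DEL-M", 1_000, 100_000),
    SizeClass("DEL-L", 100_000, 1_000_000),
)
DUP_BINS = (
    SizeClass("DUP-S", 100, 1_000),
    SizeClass("DUP-M", 1_000, 100_000),
    SizeClass("DUP-L", 100_000, 1_000_000),
)
INS_CLASS = SizeClass("INS", 0, 1_000_000)
INV_CLASS = SizeClass("INV", 0, 1_000_000)

#: Marker returned when a record's length falls outside every bin; such
#: records are excluded from size-stratified reports.
UNBINNED = "unbinned"

GENOTYPES = ("hom", "het", "unknown")
INS_CLASSES = ("MEI", "NUMT", "VEI", "unspecified")


@dataclass
class SVRecord:
    """One normalized SV call or truth variant.

    ``start``/``end`` are 0-based half-open reference coordinates. For
    DEL/DUP/INV the length equals ``end - start`` unless explicitly given.
    INS records are stored as 1 bp anchors (``end = start + 1``) with an
    independent length, which may be None when the caller does not report
    the inserted length. ``rss`` is the supporting-read count (Reads
    Supporting SV) used for threshold filtering.
    """

    chrom: str
    start: int
    end: int
    svtype: SVType
    length: Optional[int] = None
    genotype: str = "unknown"
    rss: int = 0
    ins_class: str = "unspecified"
    source_id: str = ""
    id: int = field(default_factory=lambda: next(_id_counter))

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise SVModelError(
                f"end < start for record {self.chrom}:{self.start}-{self.end}"
            )
        if self.svtype is SVType.INS:
            self.end = self.start + 1
        elif self.length is None:
            self.length = self.end - self.start
        if self.rss < 0:
            raise SVModelError("rss must be non-negative")
        if self.genotype not in GENOTYPES:
            raise SVModelError(f"unknown genotype label {self.genotype!r}")

    @property
    def span(self) -> int:
        """Reference footprint in bp (1 for INS anchors)."""
        return self.end - self.start

    def __hash__(self) -> int:
        return hash(self.id)


@dataclass
class MatchCriteria:
    """Thresholds governing call-to-truth matching.

    ``mode='simulated'`` matches DEL/DUP/INV at ``recip_frac`` reciprocal
    overlap (default 0.8), relaxed to ``recip_frac_small`` (default 0.6)
    when the reference variant is at most ``small_size`` bp. ``mode='real'``
    uses a single 0.5 threshold. INS calls match when insertion points lie
    within ``ins_bp_window`` bp (default 200). ``length_ratio_mode``
    additionally requires call length / reference length within
    ``length_ratio_bounds`` for records that report a defined length.
    """

    mode: str = "simulated"
    recip_frac: float = 0.8
    recip_frac_small: float = 0.6
    small_size: int = 1_000
    ins_bp_window: int = 200
    length_ratio_mode: bool = False
    length_ratio_bounds: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.mode not in ("simulated", "real"):
            raise SVModelError(f"mode must be 'simulated' or 'real', got {self.mode!r}")
        for f in (self.recip_frac, self.recip_frac_small):
            if not 0.0 < f <= 1.0:
                raise SVModelError("reciprocal fractions must lie in (0, 1]")
        if self.ins_bp_window < 0:
            raise SVModelError("ins_bp_window must be >= 0")
        low, high = self.length_ratio_bounds
        if not (low <= 1.0 <= high):
            raise SVModelError("length_ratio_bounds must bracket 1.0")

    @classmethod
    def for_mode(cls, mode: str, **kw) -> "MatchCriteria":
        if mode == "real":
            return cls(mode="real", recip_frac=0.5, recip_frac_small=0.5, **kw)
        return cls(mode="simulated", **kw)

    def threshold_for(self, ref_span: int) -> float:
        """Reciprocal-overlap threshold applicable to a reference of this size.

        The relaxation for small variants keys on the reference length.
        """
        if self.mode == "real":
            return self.recip_frac
        return self.recip_frac_small if ref_span <= self.small_size else self.recip_frac


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """Reciprocal overlap fraction min(ovl/len(a), ovl/len(b)) in [0, 1].

    Records on different chromosomes overlap by 0 (never an error);
    zero-length records are malformed input and raise.
    """
    if a.svtype is SVType.INS or b.svtype is SVType.INS:
        raise SVModelError("reciprocal_overlap is undefined for INS records")
    if a.span == 0 or b.span == 0:
        raise SVModelError("zero-length record in reciprocal_overlap")
    if a.chrom != b.chrom:
        return 0.0
    ovl = min(a.end, b.end) - max(a.start, b.start)
    if ovl <= 0:
        return 0.0
    return min(ovl / a.span, ovl / b.span)


def size_class_of(rec: SVRecord) -> SizeClass | str:
    """Assign a DEL/DUP record to its size bin by length.

    Returns :data:`UNBINNED` when the length falls outside every bin.
    INS/INV records map to their single type-wide category.
    """
    if rec.svtype is SVType.INS:
        return INS_CLASS
    if rec.svtype is SVType.INV:
        return INV_CLASS
    bins = DEL_BINS if rec.svtype is SVType.DEL else DUP_BINS
    length = rec.length if rec.length is not None else rec.span
    for i, bin_ in enumerate(bins):
        if bin_.contains(length, final=(i == len(bins) - 1)):
            return bin_
    return UNBINNED


def bp_distance(a: SVRecord, b: SVRecord) -> int:
    """Absolute distance in bp between two insertion points."""
    if a.svtype is not SVType.INS or b.svtype is not SVType.INS:
        raise SVModelError("bp_distance requires two INS records")
    if a.chrom != b.chrom:
        raise SVModelError("bp_distance requires records on the same chromosome")
    return abs(a.start - b.start)
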