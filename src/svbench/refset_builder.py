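"""Construction of a merged truth ReferenceSet from multiple sources.

The pipeline order is: per-source short-variant removal → cross-source
duplicate removal → merge keeping the longer record → final size filter.
Sources are processed pairwise in priority order. Deduplication and merging
operate within DEL/DUP/INV only (never across types), and the final set is
deliberately *not* forced to be non-redundant: residual overlaps that fall
below the dedup thresholds are kept and reported, since there is no basis
for deciding which of two partially-overlapping records is the inaccurate
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from svbench.io_calls import ReferenceSet
from svbench.sv_model import SVModelError, SVRecord, SVType, reciprocal_overlap

_OVERLAP_TYPES = (SVType.DEL, SVType.DUP, SVType.INV)


@dataclass
class MergePolicy:
    """Thresholds for cross-source deduplication and merging.

    Defaults follow the multi-source truth-set recipe: duplicates removed at
    >= 95% reciprocal overlap (90% for variants > 1 kb), overlapping
    deletions merged at >= 70% keeping the longer record, short
    DELs/INSs (< 1 kb or unknown length) dropped from a designated
    lower-priority source, and non-INS variants < 50 bp removed at the end.
    """

    dedup_frac: float = 0.95
    dedup_frac_large: float = 0.90
    large_size: int = 1_000
    merge_frac: float = 0.70
    min_size: int = 50
    short_del_cut: int = 1_000
    priority: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for f in (self.dedup_frac, self.dedup_frac_large, self.merge_frac):
            if not 0.0 < f <= 1.0:
                raise SVModelError("merge-policy fractions must lie in (0, 1]")
        if self.min_size < 0:
            raise SVModelError("min_size must be >= 0")

    def dedup_threshold(self, a: SVRecord, b: SVRecord) -> float:
        span = max(a.span, b.span)
        return self.dedup_frac_large if span > self.large_size else self.dedup_frac


@dataclass
class MergeAudit:
    """Per-rule removal counts accumulated across the pipeline."""

    removed: dict[str, int] = field(default_factory=dict)
    residual_overlaps: int = 0

    def bump(self, rule: str, n: int = 1) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + n


def drop_short_from_source(
    src: ReferenceSet,
    cut: int,
    types: Sequence[SVType] = (SVType.DEL, SVType.INS),
    audit: Optional[MergeAudit] = None,
) -> ReferenceSet:
    """Remove short DELs and INSs from one (lower-confidence) source.

    DELs shorter than ``cut`` and INSs shorter than ``cut`` or with unknown
    length are dropped; other sources are expected to cover those size
    ranges more reliably.
    """
    if cut <= 0:
        raise SVModelError("cut must be > 0")
    kept = []
    dropped = 0
    for rec in src:
        if rec.svtype in types:
            if rec.length is None or rec.length < cut:
                dropped += 1
                continue
        kept.append(rec)
    if audit is not None:
        audit.bump("short_from_source", dropped)
    return src.replaced(kept)


def dedup_across(
    a: ReferenceSet,
    b: ReferenceSet,
    policy: MergePolicy,
    audit: Optional[MergeAudit] = None,
) -> ReferenceSet:
    """Remove near-identical lower-priority records across two sources.

    ``a`` is the higher-priority source. DEL/DUP/INV records of ``b`` with
    reciprocal overlap >= the applicable threshold (95%, or 90% when either
    record exceeds 1 kb) against a same-type record of ``a`` are removed.
    Returns the filtered ``b``; removal counts go to ``audit``.
    """
    kept = []
    removed = 0
    for rec in b:
        if rec.svtype in _OVERLAP_TYPES:
            dup = any(
                other.svtype is rec.svtype
                and reciprocal_overlap(rec, other) >= policy.dedup_threshold(rec, other)
                for other in a.overlapping(rec.chrom, rec.start, rec.end)
                if other.svtype in _OVERLAP_TYPES
            )
            if dup:
                removed += 1
                continue
        kept.append(rec)
    if audit is not None:
        audit.bump("dedup_across", removed)
    return b.replaced(kept)


def merge_keep_longer(
    a: ReferenceSet,
    b: ReferenceSet,
    frac: float = 0.70,
    audit: Optional[MergeAudit] = None,
    types: Sequence[SVType] = (SVType.DEL,),
) -> ReferenceSet:
    """Union of two sources, keeping only the longer of overlapping records.

    For same-type pairs (default: DELs) with reciprocal overlap >= ``frac``,
    the shorter record is removed; on equal lengths the higher-priority
    (``a``) record wins. All other records pass through.
    """
    if not 0.0 < frac <= 1.0:
        raise SVModelError("frac must lie in (0, 1]")
    # Only cross-source pairs are compared: overlaps *within* one source are
    # residual truth-set redundancy and deliberately survive the merge
    # (merging a set with itself is the identity). Records shared between
    # the inputs (same id) are taken once.
    a_ids = {rec.id for rec in a}
    b_only = [r for r in b if r.id not in a_ids]
    removed_ids: set[int] = set()
    for rec in b_only:
        if rec.svtype not in types:
            continue
        for other in a.overlapping(rec.chrom, rec.start, rec.end):
            if (
                other.svtype is not rec.svtype
                or other.id in removed_ids
                or other.id == rec.id
            ):
                continue
            if reciprocal_overlap(rec, other) >= frac:
                la = other.length or other.span
                lb = rec.length or rec.span
                if lb > la:
                    removed_ids.add(other.id)
                else:  # shorter, or tie: higher-priority source wins
                    removed_ids.add(rec.id)
                    break
    if audit is not None:
        audit.bump("merge_shorter_removed", len(removed_ids))
    combined = list(a) + b_only
    out = ReferenceSet(
        (r for r in combined if r.id not in removed_ids),
        source_id=a.source_id or b.source_id,
    )
    return out


def finalize(
    ref: ReferenceSet,
    policy: MergePolicy,
    audit: Optional[MergeAudit] = None,
) -> ReferenceSet:
    """Final size filter: non-INS records shorter than ``min_size`` removed.

    Also counts residual same-type overlaps left in the set (they are kept,
    not resolved) into the audit.
    """
    kept, removed = [], 0
    for rec in ref:
        if rec.svtype is not SVType.INS and (rec.length or rec.span) < policy.min_size:
            removed += 1
            continue
        kept.append(rec)
    out = ref.replaced(kept)
    if audit is not None:
        audit.bump("final_min_size", removed)
        audit.residual_overlaps = count_residual_overlaps(out)
    return out


def count_residual_overlaps(ref: ReferenceSet) -> int:
    """Number of same-type record pairs that still intersect in the set."""
    n = 0
    for rec in ref:
        if rec.svtype not in _OVERLAP_TYPES:
            continue
        for other in ref.overlapping(rec.chrom, rec.start, rec.end):
            if other.id > rec.id and other.svtype is rec.svtype:
                n += 1
    return n


def build_reference(
    sources: Sequence[ReferenceSet],
    policy: Optional[MergePolicy] = None,
    short_cut_sources: Sequence[str] = (),
) -> tuple[ReferenceSet, MergeAudit]:
    """Run the full pipeline over sources ordered highest priority first.

    ``short_cut_sources`` names sources whose short DELs/INSs are dropped
    before merging. Sources are merged pairwise in priority order.
    """
    if not sources:
        raise SVModelError("at least one source required")
    policy = policy or MergePolicy()
    audit = MergeAudit()
    prepared = [
        drop_short_from_source(s, policy.short_del_cut, audit=audit)
        if s.source_id in short_cut_sources
        else s
        for s in sources
    ]
    merged = prepared[0]
    for nxt in prepared[1:]:
        nxt = dedup_across(merged, nxt, policy, audit=audit)
        merged = merge_keep_longer(merged, nxt, policy.merge_frac, audit=audit)
    merged = finalize(merged, policy, audit=audit)
    return merged, audit
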