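"""Call-to-truth matching and every accuracy statistic of the benchmark.

Matching is greedy one-to-one: candidate call/reference pairs are ranked by
descending reciprocal overlap (ascending breakpoint distance for
insertions) and consumed so that each call validates at most one reference
and vice versa. This is the conservative reading of overlap-based truth
matching — it can never produce more true positives than reference
variants — and on non-ambiguous inputs it coincides with the optimal
bipartite matching (a property the test suite asserts).

Insertions and duplications can be complementary descriptions of the same
event, so unmatched INS calls are retried against DUP references (and
symmetrically); each such cross-type hit increments both the TP count and
the reference denominator of the *call's* type, so precision and recall
both see the hit.

All percentage metrics are reported on a 0–100 scale. Metrics with a zero
denominator are ``None`` (NaN in tabular output), never silently 0 or 100.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from svbench.io_calls import CallSet, ReferenceSet, filter_by_rss
from svbench.sv_model import (
    INS_CLASS,
    INV_CLASS,
    DEL_BINS,
    DUP_BINS,
    UNBINNED,
    MatchCriteria,
    SVModelError,
    SVRecord,
    SVType,
    bp_distance,
    reciprocal_overlap,
    size_class_of,
)

logger = logging.getLogger(__name__)

#: Per-type recall normalization index for the modified F-measure. Real-data
#: recall runs well below simulated recall because the truth set carries an
#: excess of overlapped reference variants; Nrc rescales it per SV type.
DEFAULT_NRC = {SVType.DEL: 2.9, SVType.DUP: 4.0, SVType.INS: 2.4, SVType.INV: 2.4}

#: Expected per-type SV counts in one human genome, used to cap the RSS
#: threshold search.
DEFAULT_EXPECTED_COUNTS = {
    SVType.DEL: 3500,
    SVType.DUP: 550,
    SVType.INS: 3000,
    SVType.INV: 100,
}


@dataclass
class EvalConfig:
    """Evaluation-wide configuration: matching criteria plus scoring constants."""

    mode: str = "simulated"
    criteria: Optional[MatchCriteria] = None
    nrc: dict = field(default_factory=lambda: dict(DEFAULT_NRC))
    expected_counts: dict = field(default_factory=lambda: dict(DEFAULT_EXPECTED_COUNTS))
    rss_cap_frac: float = 0.9

    def __post_init__(self) -> None:
        if self.mode not in ("simulated", "real"):
            raise SVModelError("EvalConfig.mode must be 'simulated' or 'real'")
        if self.criteria is None:
            self.criteria = MatchCriteria.for_mode(self.mode)
        if any(v <= 0 for v in self.nrc.values()):
            raise SVModelError("Nrc values must be positive")
        if any(v <= 0 for v in self.expected_counts.values()):
            raise SVModelError("expected counts must be positive")


@dataclass
class TPLink:
    call: SVRecord
    ref: SVRecord
    score: float  # reciprocal-overlap fraction, or -distance for INS
    bp_error: float
    length_error: Optional[float]
    cross_type: bool = False


@dataclass
class MatchResult:
    """TP linkage between a call set and a reference set."""

    tp_links: list[TPLink] = field(default_factory=list)
    fp: list[SVRecord] = field(default_factory=list)
    fn: list[SVRecord] = field(default_factory=list)
    #: per call-type count of cross-type hits (INS calls on DUP refs, etc.)
    cross_type_hits: dict = field(default_factory=dict)
    n_calls: dict = field(default_factory=dict)
    n_refs: dict = field(default_factory=dict)

    def tp_count(self, svtype: Optional[SVType] = None) -> int:
        return sum(
            1 for l in self.tp_links if svtype is None or l.call.svtype is svtype
        )

    def call_count(self, svtype: Optional[SVType] = None) -> int:
        if svtype is None:
            return sum(self.n_calls.values())
        return self.n_calls.get(svtype, 0)

    def ref_count(self, svtype: Optional[SVType] = None) -> int:
        """Reference denominator, including cross-type adjustment."""
        if svtype is None:
            return sum(self.ref_count(t) for t in self.n_refs)
        return self.n_refs.get(svtype, 0) + self.cross_type_hits.get(svtype, 0)


def _bp_error(call: SVRecord, ref: SVRecord) -> float:
    """Breakpoint error: mean of |start error| and |end error| for
    DEL/DUP/INV, |insertion-point error| for INS."""
    if call.svtype is SVType.INS or ref.svtype is SVType.INS:
        if call.svtype is SVType.INS and ref.svtype is SVType.INS:
            return float(abs(call.start - ref.start))
        # cross-type: distance from insertion point to nearest breakpoint
        pt, iv = (call, ref) if call.svtype is SVType.INS else (ref, call)
        return float(min(abs(pt.start - iv.start), abs(pt.start - iv.end)))
    return (abs(call.start - ref.start) + abs(call.end - ref.end)) / 2.0


def _length_error(call: SVRecord, ref: SVRecord) -> Optional[float]:
    if call.length is None or ref.length is None:
        return None
    return float(abs(call.length - ref.length))


def _length_ratio_ok(call: SVRecord, ref: SVRecord, criteria: MatchCriteria) -> bool:
    if not criteria.length_ratio_mode:
        return True
    if call.length is None or ref.length is None or ref.length == 0:
        return True  # callers without defined lengths are not penalized
    low, high = criteria.length_ratio_bounds
    return low <= call.length / ref.length <= high


def _greedy_assign(pairs: list[tuple[float, SVRecord, SVRecord]]) -> list[tuple[float, SVRecord, SVRecord]]:
    """One-to-one greedy assignment over (score, call, ref), best score first.

    Ties break deterministically on record ids.
    """
    pairs = sorted(pairs, key=lambda p: (-p[0], p[1].id, p[2].id))
    used_calls: set[int] = set()
    used_refs: set[int] = set()
    out = []
    for score, call, ref in pairs:
        if call.id in used_calls or ref.id in used_refs:
            continue
        used_calls.add(call.id)
        used_refs.add(ref.id)
        out.append((score, call, ref))
    return out


def match_calls(calls: CallSet, ref: ReferenceSet, cfg: EvalConfig) -> MatchResult:
    """Match calls against the truth set under the configured criteria.

    DEL/DUP/INV match by reciprocal overlap at the mode-dependent threshold
    (simulated: 80%, relaxed to 60% for references <= 1 kb; real: 50%);
    INS match when insertion points lie within the window (default 200 bp).
    Greedy one-to-one assignment; leftover INS calls retry against DUP
    references and vice versa.
    """
    criteria = cfg.criteria
    result = MatchResult()
    matched_call_ids: set[int] = set()
    matched_ref_ids: set[int] = set()

    for svtype in SVType:
        type_calls = calls.of_type(svtype)
        type_refs = ref.of_type(svtype)
        result.n_calls[svtype] = len(type_calls)
        result.n_refs[svtype] = len(type_refs)
        ref_index = ReferenceSet(type_refs, source_id=ref.source_id)
        pairs: list[tuple[float, SVRecord, SVRecord]] = []
        if svtype is SVType.INS:
            for c in type_calls:
                for r in ref_index.near(c.chrom, c.start, criteria.ins_bp_window):
                    d = bp_distance(c, r)
                    if d <= criteria.ins_bp_window and _length_ratio_ok(c, r, criteria):
                        pairs.append((-float(d), c, r))
        else:
            for c in type_calls:
                for r in ref_index.overlapping(c.chrom, c.start, c.end):
                    f = reciprocal_overlap(c, r)
                    if f >= criteria.threshold_for(r.span) and _length_ratio_ok(
                        c, r, criteria
                    ):
                        pairs.append((f, c, r))
        for score, c, r in _greedy_assign(pairs):
            result.tp_links.append(
                TPLink(c, r, score, _bp_error(c, r), _length_error(c, r))
            )
            matched_call_ids.add(c.id)
            matched_ref_ids.add(r.id)

    # cross-type retry: INS calls against DUP refs, DUP calls against INS refs
    for call_t, ref_t in ((SVType.INS, SVType.DUP), (SVType.DUP, SVType.INS)):
        leftover_calls = [
            c for c in calls.of_type(call_t) if c.id not in matched_call_ids
        ]
        leftover_refs = ReferenceSet(
            [r for r in ref.of_type(ref_t) if r.id not in matched_ref_ids],
            source_id=ref.source_id,
        )
        pairs = []
        for c in leftover_calls:
            if call_t is SVType.INS:
                cands = leftover_refs.near(c.chrom, c.start, criteria.ins_bp_window)
            else:
                cands = leftover_refs.overlapping(
                    c.chrom, c.start - criteria.ins_bp_window,
                    c.end + criteria.ins_bp_window,
                )
            for r in cands:
                pt = c if call_t is SVType.INS else r
                iv = r if call_t is SVType.INS else c
                d = min(abs(pt.start - iv.start), abs(pt.start - iv.end))
                if d <= criteria.ins_bp_window:
                    pairs.append((-float(d), c, r))
        hits = _greedy_assign(pairs)
        if hits:
            result.cross_type_hits[call_t] = len(hits)
        for score, c, r in hits:
            result.tp_links.append(
                TPLink(c, r, score, _bp_error(c, r), None, cross_type=True)
            )
            matched_call_ids.add(c.id)
            matched_ref_ids.add(r.id)

    result.fp = [c for c in calls if c.id not in matched_call_ids]
    result.fn = [r for r in ref if r.id not in matched_ref_ids]
    return result


def precision_recall(
    m: MatchResult, svtype: Optional[SVType] = None
) -> tuple[Optional[float], Optional[float]]:
    """(precision %, recall %) with cross-type-adjusted denominators.

    ``None`` marks an undefined metric (zero calls or zero references).
    """
    tp = m.tp_count(svtype)
    call = m.call_count(svtype)
    ref = m.ref_count(svtype)
    pr = 100.0 * tp / call if call > 0 else None
    rc = 100.0 * tp / ref if ref > 0 else None
    return pr, rc


# ---------------------------------------------------------------------------
# size-stratified evaluation


@dataclass
class CategoryRow:
    source: str
    svtype: str
    size_class: str
    tp_call: int  # precision numerator: matched calls of this class
    call: int
    tp_ref: int  # recall numerator: matched references of this class
    ref: int

    @property
    def precision(self) -> Optional[float]:
        return 100.0 * self.tp_call / self.call if self.call else None

    @property
    def recall(self) -> Optional[float]:
        return 100.0 * self.tp_ref / self.ref if self.ref else None


@dataclass
class EvalReport:
    """Per (SV type x size class) accuracy table plus global error metrics."""

    source: str
    rows: list[CategoryRow] = field(default_factory=list)
    bp_rmse: dict = field(default_factory=dict)  # per SVType, bp
    length_rmse: dict = field(default_factory=dict)  # per SVType, bp
    genotype: Optional[tuple] = None  # (Precision1 %, Precision2 %, Recall %)
    mier: Optional[float] = None
    nrc: dict = field(default_factory=lambda: dict(DEFAULT_NRC))

    def row(self, svtype: str, size_class: str) -> Optional[CategoryRow]:
        for r in self.rows:
            if r.svtype == svtype and r.size_class == size_class:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            nrc = self.nrc.get(SVType[r.svtype], 1.0)
            f = (
                f_measure(r.precision, r.recall, nrc)
                if r.precision is not None and r.recall is not None
                else None
            )
            recs.append(
                {
                    "source": r.source,
                    "svtype": r.svtype,
                    "size_class": r.size_class,
                    "TP": r.tp_call,
                    "Call": r.call,
                    "TP_ref": r.tp_ref,
                    "Ref": r.ref,
                    "Pr": r.precision,
                    "Rc": r.recall,
                    "F": f,
                }
            )
        return pd.DataFrame(
            recs,
            columns=["source", "svtype", "size_class", "TP", "Call", "TP_ref",
                     "Ref", "Pr", "Rc", "F"],
        )

    def extra_metrics(self) -> dict:
        return {
            "bp_rmse": {t.value: v for t, v in self.bp_rmse.items()},
            "length_rmse": {t.value: v for t, v in self.length_rmse.items()},
            "genotype": self.genotype,
            "mier": self.mier,
        }


def _class_label(rec: SVRecord) -> str:
    sc = size_class_of(rec)
    return sc if sc == UNBINNED else sc.label


def stratified_eval(
    calls: CallSet, ref: ReferenceSet, cfg: EvalConfig
) -> EvalReport:
    """Evaluate with size stratification.

    Calls are always matched against the *full* typed reference set, never a
    size-restricted slice, because overlap search can legitimately hit a
    reference outside the call's own size range. A matched call counts
    toward precision in the call's own size class and toward recall in the
    matched reference's size class. Cross-type hits enter the per-type
    totals (the ALL row) on both sides.
    """
    m = match_calls(calls, ref, cfg)
    # the Nrc recall rescaling compensates the real truth set's excess of
    # overlapped references; simulated truth needs no compensation
    nrc = dict(cfg.nrc) if cfg.mode == "real" else {t: 1.0 for t in SVType}
    report = EvalReport(source=calls.source_id, nrc=nrc)

    for svtype in SVType:
        same_links = [
            l for l in m.tp_links if l.call.svtype is svtype and not l.cross_type
        ]
        cross = m.cross_type_hits.get(svtype, 0)
        type_calls = calls.of_type(svtype)
        type_refs = ref.of_type(svtype)
        if not type_calls and not type_refs:
            continue
        # per-type total row (cross-type hits included on both sides)
        report.rows.append(
            CategoryRow(
                calls.source_id, svtype.value, "ALL",
                len(same_links) + cross, len(type_calls),
                len(same_links) + cross, len(type_refs) + cross,
            )
        )
        if svtype in (SVType.DEL, SVType.DUP):
            bins = DEL_BINS if svtype is SVType.DEL else DUP_BINS
            for bin_ in bins:
                n_call = sum(1 for c in type_calls if _class_label(c) == bin_.label)
                n_ref = sum(1 for r in type_refs if _class_label(r) == bin_.label)
                tp_call = sum(
                    1 for l in same_links if _class_label(l.call) == bin_.label
                )
                tp_ref = sum(
                    1 for l in same_links if _class_label(l.ref) == bin_.label
                )
                report.rows.append(
                    CategoryRow(calls.source_id, svtype.value, bin_.label,
                                tp_call, n_call, tp_ref, n_ref)
                )

        # global error metrics over same-type links
        bp_errs = [l.bp_error for l in same_links]
        if bp_errs:
            report.bp_rmse[svtype] = float(np.sqrt(np.mean(np.square(bp_errs))))
        len_errs = [l.length_error for l in same_links if l.length_error is not None]
        if len_errs:
            report.length_rmse[svtype] = float(np.sqrt(np.mean(np.square(len_errs))))

    report.genotype = genotype_concordance(m, calls, ref)
    return report


# ---------------------------------------------------------------------------
# RSS threshold machinery


def sweep_rss(
    calls: CallSet,
    ref: ReferenceSet,
    cfg: EvalConfig,
    thresholds: Sequence[int],
    svtype: Optional[SVType] = None,
) -> pd.DataFrame:
    """Evaluate at each RSS threshold; one row per threshold.

    Columns: RSS, Call, TP, Pr, Rc. The Call column is non-increasing in
    RSS by construction of the filter.
    """
    if list(thresholds) != sorted(thresholds):
        raise SVModelError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        filtered = filter_by_rss(calls, t)
        m = match_calls(filtered, ref, cfg)
        pr, rc = precision_recall(m, svtype)
        rows.append(
            {
                "RSS": t,
                "Call": m.call_count(svtype),
                "TP": m.tp_count(svtype),
                "Pr": pr,
                "Rc": rc,
            }
        )
    return pd.DataFrame(rows)


def select_rss(sweep: pd.DataFrame, expected: int, cap_frac: float = 0.9) -> int:
    """Least-stringent RSS whose call count stays within the expected-count cap.

    The cap is ``cap_frac * expected`` (default 90% of the expected per-type
    SV count in one genome): the selected threshold approximates but does
    not exceed it. When no threshold satisfies the cap, the largest swept
    RSS is returned with a warning.
    """
    if sweep.empty:
        raise SVModelError("empty RSS sweep")
    cap = cap_frac * expected
    ok = sweep[sweep["Call"] <= cap]
    if ok.empty:
        warnings.warn(
            f"no RSS threshold brings calls under the cap ({cap:.0f}); "
            "returning the most stringent swept value"
        )
        return int(sweep["RSS"].max())
    return int(ok["RSS"].min())


def select_optimal_rss(sweep: pd.DataFrame) -> int:
    """RSS maximizing precision + recall; ties go to the smaller RSS."""
    if sweep.empty:
        raise SVModelError("empty RSS sweep")
    s = sweep.dropna(subset=["Pr", "Rc"])
    if s.empty:
        return int(sweep["RSS"].min())
    total = s["Pr"] + s["Rc"]
    best = total.max()
    return int(s.loc[total == best, "RSS"].min())


# ---------------------------------------------------------------------------
# scalar statistics


def f_measure(pr: float, rc: float, nrc: float = 1.0) -> float:
    """Modified F-measure F = 2*Pr*Rc*Nrc / (Pr + Rc*Nrc) * 0.01.

    Pr and Rc are percentages; Nrc is the per-type recall normalization
    index (1.0 gives the plain F-measure on a 0–1 scale). Zero precision or
    recall gives 0 by convention.
    """
    if pr < 0 or rc < 0:
        raise SVModelError("precision/recall must be non-negative")
    if pr == 0 or rc == 0:
        logger.info("f_measure: zero precision or recall; F = 0 by convention")
        return 0.0
    return 2.0 * pr * rc * nrc / (pr + rc * nrc) * 0.01


def normalized_f(values: dict) -> dict:
    """Each algorithm's F divided by the category mean F (mean of output = 1)."""
    if not values:
        raise SVModelError("normalized_f needs at least one algorithm")
    mean = sum(values.values()) / len(values)
    if mean == 0:
        return {k: None for k in values}
    return {k: v / mean for k, v in values.items()}


def combined_precision(
    pr_sim: float, pr_real: float, mpr_sim: float, mpr_real: float
) -> Optional[float]:
    """Combined precision score cPr = Pr(sim)*Pr(real) / (mPr(sim)*mPr(real)).

    Integrates simulated- and real-data precision, each normalized by its
    category mean. Undefined (None) when either mean is zero.
    """
    if mpr_sim == 0 or mpr_real == 0:
        return None
    return (pr_sim * pr_real) / (mpr_sim * mpr_real)


def coefficient_of_variation(values: Sequence[float]) -> Optional[float]:
    """Sample-SD / mean; None when the mean is zero. Requires n >= 2."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise SVModelError("CV requires at least two values")
    mean = values.mean()
    if mean == 0:
        return None
    return float(values.std(ddof=1) / mean)


def spearman_rank(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Spearman r_s = 1 - 6*sum(d^2)/(n^3 - n) for tie-free rank vectors.

    Inputs must be permutations of 1..n; ties require pre-ranking with an
    explicit tie rule before calling (the closed form assumes none).
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise SVModelError("spearman_rank needs two equal-length vectors, n >= 2")
    n = a.size
    for v in (a, b):
        if len(set(v.tolist())) != n:
            raise SVModelError(
                "ties present: pre-rank the data with a documented tie rule"
            )
    d2 = float(np.sum((a - b) ** 2))
    return 1.0 - 6.0 * d2 / (n**3 - n)


def rmse(paired_values: Iterable[tuple[float, float]]) -> Optional[float]:
    """Root mean squared error sqrt(mean((called - reference)^2))."""
    diffs = [c - r for c, r in paired_values]
    if not diffs:
        return None
    return float(np.sqrt(np.mean(np.square(diffs))))


# ---------------------------------------------------------------------------
# genotype and trio analyses


def genotype_concordance(
    m: MatchResult, calls: CallSet, ref: ReferenceSet
) -> Optional[tuple]:
    """(Precision1 %, Precision2 %, Recall %) of genotype calls over TP sites.

    Precision1 divides correct genotypes by all truly called sites,
    Precision2 by truly called sites that carry a genotype, and recall by
    the total number of reference sites. None when the reference has no
    genotype information.
    """
    links = [
        l for l in m.tp_links
        if not l.cross_type and l.ref.genotype in ("hom", "het")
    ]
    n_ref = sum(1 for r in ref if r.genotype in ("hom", "het"))
    if n_ref == 0:
        return None
    tp_sites = len(links)
    genotyped = [l for l in links if l.call.genotype in ("hom", "het")]
    correct = sum(1 for l in genotyped if l.call.genotype == l.ref.genotype)
    p1 = 100.0 * correct / tp_sites if tp_sites else None
    p2 = 100.0 * correct / len(genotyped) if genotyped else None
    rc = 100.0 * correct / n_ref
    return (p1, p2, rc)


def _matches_parent(
    child_rec: SVRecord, parent: CallSet, frac: float, window: int
) -> bool:
    if child_rec.svtype is SVType.INS:
        return any(
            r.svtype is SVType.INS and bp_distance(child_rec, r) <= window
            for r in parent.near(child_rec.chrom, child_rec.start, window)
        )
    return any(
        r.svtype is child_rec.svtype and reciprocal_overlap(child_rec, r) >= frac
        for r in parent.overlapping(child_rec.chrom, child_rec.start, child_rec.end)
    )


def mendelian_error_rate(
    child: CallSet,
    father: CallSet,
    mother: CallSet,
    frac: float = 0.5,
    ins_window: int = 200,
    svtype: Optional[SVType] = None,
) -> Optional[float]:
    """MIER %: child calls matching neither parent, as a share of all child calls.

    A child call matches a parent when the parent has a same-type call with
    >= 50% reciprocal overlap (<= 200 bp insertion-point distance for INS).
    Child calls present in neither parent are Mendelian-inheritance errors
    (or de novo variants, which are rare enough to neglect).
    """
    records = child.records if svtype is None else child.of_type(svtype)
    if not records:
        return None
    errors = sum(
        1
        for c in records
        if not _matches_parent(c, father, frac, ins_window)
        and not _matches_parent(c, mother, frac, ins_window)
    )
    return 100.0 * errors / len(records)
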