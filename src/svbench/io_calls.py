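"""Reading, normalizing and writing SV call sets and evaluation reports.

Heterogeneous caller VCF dialects (SVTYPE INFO keys, symbolic ALTs,
REF/ALT length differences) and BED-like interval tables are normalized
into :class:`CallSet` / :class:`ReferenceSet` collections of
:class:`~svbench.sv_model.SVRecord`, indexed per chromosome for interval
queries. Every record dropped during normalization is counted by reason —
input records always equal kept plus dropped.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy.stats import rankdata

from svbench.sv_model import SVModelError, SVRecord, SVType

logger = logging.getLogger(__name__)

METHOD_CLASSES = ("RP", "SR", "RD", "AS", "LR", "CB")

#: ALT / SVTYPE labels that denote breakends or translocations.
_BND_LABELS = {"BND", "TRA", "CTX", "ITX"}


class CallSet:
    """Indexed collection of SVRecords from one caller or truth source."""

    def __init__(
        self,
        records: Iterable[SVRecord] = (),
        source_id: str = "",
        method_class: Optional[str] = None,
        drop_counts: Optional[Counter] = None,
    ):
        if method_class is not None and method_class not in METHOD_CLASSES:
            raise SVModelError(f"unknown method class {method_class!r}")
        self.source_id = source_id
        self.method_class = method_class
        self.records: list[SVRecord] = []
        self.drop_counts: Counter = drop_counts if drop_counts is not None else Counter()
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SVRecord) -> None:
        rec.source_id = rec.source_id or self.source_id
        self.records.append(rec)
        self._trees.setdefault(rec.chrom, IntervalTree()).addi(
            rec.start, rec.end, rec
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def of_type(self, svtype: SVType) -> list[SVRecord]:
        return [r for r in self.records if r.svtype is svtype]

    def overlapping(self, chrom: str, start: int, end: int) -> list[SVRecord]:
        """Records whose interval intersects [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def near(self, chrom: str, pos: int, window: int) -> list[SVRecord]:
        """Records whose interval intersects [pos - window, pos + window]."""
        return self.overlapping(chrom, pos - window, pos + window + 1)

    def replaced(self, records: Iterable[SVRecord]) -> "CallSet":
        """New CallSet with the same identity but different records."""
        return CallSet(records, self.source_id, self.method_class)


#: A truth collection has the same structure and behaviour as a call set.
ReferenceSet = CallSet


@dataclass
class NormalizationRules:
    """Normalization and filtering policy applied at ingestion.

    ``cnv_reassign`` expands CNV records into one DEL plus one DUP over the
    same interval (the type is ambiguous from depth evidence alone);
    ``drop_bnd`` removes breakend/translocation records. Non-INS records
    outside [min_size, max_size] are excluded with a logged count. The
    ``rss_rule`` names how supporting-read counts are derived from record
    annotations (see :func:`extract_rss`).
    """

    drop_bnd: bool = True
    cnv_reassign: bool = True
    exclude_chroms: tuple[str, ...] = ()
    min_size: int = 50
    max_size: int = 1_000_000
    rss_rule: str = "sum"
    rss_fields: tuple[str, ...] = ("PE", "SR", "RSS")
    rss_levels: int = 10
    strip_chr_prefix: bool = True

    def __post_init__(self) -> None:
        if self.min_size < 0:
            raise SVModelError("min_size must be >= 0")

    @classmethod
    def for_real_data(cls, **kw) -> "NormalizationRules":
        """Real-data profile: the Y chromosome is excluded from evaluation."""
        kw.setdefault("exclude_chroms", ("Y", "chrY"))
        return cls(**kw)

    def norm_chrom(self, chrom: str) -> str:
        if self.strip_chr_prefix and chrom.startswith("chr"):
            return chrom[3:]
        return chrom


def extract_rss(
    annotations: dict,
    rule: str = "sum",
    fields: Sequence[str] = ("PE", "SR"),
    levels: int = 10,
    all_scores: Optional[Sequence[float]] = None,
    score: Optional[float] = None,
) -> int:
    """Derive an integer RSS (supporting-read count) from record annotations.

    Rules:

    ``sum``
        Sum of the named support fields (e.g. paired-end plus split-read
        counts). Missing fields contribute 0 with a warning.
    ``field``
        A single named support field.
    ``quantile_rank``
        For callers reporting only a score or depth statistic: the score's
        empirical-CDF level among ``all_scores``, mapped onto
        ``1..levels`` (ceil(levels * rank / n), max-tie ranks). Monotone in
        the underlying score and invariant under monotone rescaling.
    """
    if rule in ("sum", "field"):
        use = fields[:1] if rule == "field" else fields
        total = 0
        for f in use:
            v = annotations.get(f)
            if v is None:
                warnings.warn(f"missing RSS annotation {f!r}; treated as 0")
                continue
            if isinstance(v, (tuple, list)):
                v = v[0]
            total += int(v)
        return max(total, 0)
    if rule == "quantile_rank":
        if all_scores is None or score is None:
            raise SVModelError("quantile_rank rule needs score and all_scores")
        ranks = rankdata(all_scores, method="max")
        # rank of `score` within the pooled scores
        r = int(ranks[list(all_scores).index(score)])
        return int(math.ceil(levels * r / len(all_scores)))
    raise SVModelError(f"unknown RSS rule {rule!r}")


def quantile_rank_rss(scores: Sequence[float], levels: int = 10) -> np.ndarray:
    """Vectorized quantile-rank RSS for a whole call set's scores."""
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores, method="max")
    return np.ceil(levels * ranks / len(scores)).astype(int)


def _info_get(info, key):
    """info.get tolerant of keys absent from the VCF header."""
    try:
        v = info.get(key)
    except (KeyError, ValueError):
        return None
    return v[0] if isinstance(v, tuple) else v


def _infer_svtype(variant: pysam.VariantRecord) -> Optional[str]:
    info = variant.info
    if "SVTYPE" in info:
        svt = info["SVTYPE"]
        if isinstance(svt, tuple):
            svt = svt[0]
        return str(svt)
    for alt in variant.alts or ():
        if alt.startswith("<") and alt.endswith(">"):
            return alt.strip("<>").split(":")[0]
        if "[" in alt or "]" in alt:
            return "BND"
    if variant.alts and variant.ref:
        diff = len(variant.alts[0]) - len(variant.ref)
        if diff <= -50:
            return "DEL"
        if diff >= 50:
            return "INS"
    return None


def _parse_gt(variant: pysam.VariantRecord) -> str:
    if len(variant.samples) == 0:
        return "unknown"
    gt = variant.samples[0].get("GT")
    if gt is None or any(a is None for a in gt):
        return "unknown"
    alts = [a for a in gt if a not in (None, 0)]
    if len(alts) == 0:
        return "unknown"
    return "hom" if len(alts) == len(gt) else "het"


def _records_from_variant(
    variant: pysam.VariantRecord, rules: NormalizationRules
) -> tuple[list[SVRecord], Optional[str]]:
    """Normalize one VCF record; returns (records, drop_reason)."""
    raw_type = _infer_svtype(variant)
    if raw_type is None:
        return [], "no_inferable_type"
    raw_type = raw_type.upper()
    if raw_type in _BND_LABELS:
        if rules.drop_bnd:
            return [], "bnd"
        return [], "unsupported_type"

    chrom = rules.norm_chrom(variant.chrom)
    if chrom in rules.exclude_chroms or variant.chrom in rules.exclude_chroms:
        return [], "excluded_chrom"
    start = variant.start  # pysam: 0-based
    info = variant.info
    svlen = _info_get(info, "SVLEN")
    length = abs(int(svlen)) if svlen is not None else None
    # Dialects disagree on END vs SVLEN padding; SVLEN wins when present so
    # that POS/SVLEN/END triples stay self-consistent after normalization.
    if length is not None and raw_type != "INS":
        end = start + length
    else:
        end = int(variant.stop)  # resolves the END INFO key when present

    gt = _parse_gt(variant)

    if raw_type == "CNV":
        if not rules.cnv_reassign:
            return [], "unsupported_type"
        types = [SVType.DEL, SVType.DUP]
    elif raw_type in SVType.__members__:
        types = [SVType[raw_type]]
    else:
        return [], "unsupported_type"

    # RSS from annotations; format-field support (PE/SR etc.) may live in
    # INFO or in the first sample depending on the caller.
    ann = dict(info)
    if len(variant.samples) > 0:
        for k, v in variant.samples[0].items():
            if k != "GT":
                ann.setdefault(k, v)
    if rules.rss_rule in ("sum", "field"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rss = extract_rss(ann, rules.rss_rule, rules.rss_fields)
    else:
        rss = 0  # provisional; assigned set-wide afterwards

    out = []
    for svtype in types:
        if svtype is SVType.INS:
            rec_len = length  # may be None: unknown inserted length
            rec = SVRecord(chrom, start, start + 1, svtype, rec_len,
                           genotype=gt, rss=rss)
        else:
            if end <= start and length:
                end = start + length
            if end <= start:
                return [], "zero_length"
            rec = SVRecord(chrom, start, end, svtype, length or end - start,
                           genotype=gt, rss=rss)
            if rec.length < rules.min_size or rec.length > rules.max_size:
                return [], "size_out_of_range"
        ins_cls = _info_get(info, "INSCLASS")
        if ins_cls:
            rec.ins_class = str(ins_cls)
        out.append(rec)
    return out, None


def read_vcf_calls(
    path: str | Path,
    rules: Optional[NormalizationRules] = None,
    source_id: Optional[str] = None,
    method_class: Optional[str] = None,
) -> CallSet:
    """Read a caller/truth VCF into a normalized CallSet.

    Coordinates convert to 0-based half-open; lengths resolve from SVLEN or
    END−POS; the genotype is parsed from the first sample's GT (multi-sample
    VCFs are rejected — the toolkit evaluates single-sample callers).
    Dropped records are counted by reason in ``CallSet.drop_counts``.
    """
    rules = rules or NormalizationRules()
    path = Path(path)
    cs = CallSet(source_id=source_id or path.stem, method_class=method_class)
    # pysam warns about VCFs with no contig header lines; harmless here.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
    if len(vf.header.samples) > 1:
        raise SVModelError(
            f"{path} has {len(vf.header.samples)} samples; svbench evaluates "
            "single-sample call sets"
        )
    pending_scores: list[float] = []
    pending_records: list[SVRecord] = []
    for variant in vf:
        recs, reason = _records_from_variant(variant, rules)
        if reason is not None:
            cs.drop_counts[reason] += 1
            if reason == "no_inferable_type":
                logger.warning("dropped record with no inferable SV type at %s:%s",
                               variant.chrom, variant.pos)
            continue
        for rec in recs:
            if rules.rss_rule == "quantile_rank":
                pending_scores.append(variant.qual if variant.qual is not None else 0.0)
                pending_records.append(rec)
            cs.add(rec)
    vf.close()
    if rules.rss_rule == "quantile_rank" and pending_records:
        for rec, rss in zip(pending_records,
                            quantile_rank_rss(pending_scores, rules.rss_levels)):
            rec.rss = int(rss)
    return cs


_BED_COLS = ("chrom", "start", "end", "svtype", "length", "genotype", "rss")


def read_bed_calls(
    path: str | Path,
    rules: Optional[NormalizationRules] = None,
    source_id: Optional[str] = None,
    method_class: Optional[str] = None,
) -> CallSet:
    """Read a BED-like TSV (chrom, start, end, type[, length, gt, rss])."""
    rules = rules or NormalizationRules()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: df.shape[1]]
    cs = CallSet(source_id=source_id or path.stem, method_class=method_class)
    for row in df.itertuples(index=False):
        svt = str(row.svtype).upper()
        if svt in _BND_LABELS:
            cs.drop_counts["bnd"] += 1
            continue
        if svt not in SVType.__members__:
            cs.drop_counts["unsupported_type"] += 1
            continue
        svtype = SVType[svt]
        chrom = rules.norm_chrom(str(row.chrom))
        if chrom in rules.exclude_chroms:
            cs.drop_counts["excluded_chrom"] += 1
            continue
        length = int(row.length) if hasattr(row, "length") and not pd.isna(row.length) else None
        gt = str(row.genotype) if hasattr(row, "genotype") else "unknown"
        if gt not in ("hom", "het"):
            gt = "unknown"
        rss = int(row.rss) if hasattr(row, "rss") and not pd.isna(row.rss) else 0
        rec = SVRecord(chrom, int(row.start), int(row.end), svtype, length,
                       genotype=gt, rss=rss)
        if svtype is not SVType.INS and not (
            rules.min_size <= rec.length <= rules.max_size
        ):
            cs.drop_counts["size_out_of_range"] += 1
            continue
        cs.add(rec)
    return cs


def filter_by_rss(cs: CallSet, threshold: int) -> CallSet:
    """Retain records with rss >= threshold (count is monotone in threshold)."""
    if threshold < 0:
        raise SVModelError("RSS threshold must be >= 0")
    return cs.replaced(r for r in cs.records if r.rss >= threshold)


_GT_CODE = {"hom": "1/1", "het": "0/1", "unknown": "./."}


def write_vcf(cs: CallSet, path: str | Path, contigs: Optional[dict[str, int]] = None) -> None:
    """Write a normalized CallSet as a single-sample VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_meta("source", "svbench")
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=RSS,Number=1,Type=Integer,Description="Reads supporting SV">')
    header.add_line('##INFO=<ID=INSCLASS,Number=1,Type=String,Description="Insertion class">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = contigs or {c: max((r.end for r in cs.records if r.chrom == c), default=1) + 1000
                         for c in sorted({r.chrom for r in cs.records})}
    for chrom, ln in chroms.items():
        header.add_line(f"##contig=<ID={chrom},length={ln}>")
    header.add_sample(cs.source_id or "SAMPLE")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(str(header))
        for rec in sorted(cs.records, key=lambda r: (r.chrom, r.start)):
            svlen = rec.length if rec.length is not None else "."
            info = f"SVTYPE={rec.svtype.value};END={rec.end};RSS={rec.rss}"
            if rec.length is not None:
                sign = -1 if rec.svtype is SVType.DEL else 1
                info += f";SVLEN={sign * rec.length}"
            if rec.ins_class != "unspecified":
                info += f";INSCLASS={rec.ins_class}"
            fh.write(
                f"{rec.chrom}\t{rec.start + 1}\t.\tN\t<{rec.svtype.value}>\t.\tPASS\t"
                f"{info}\tGT\t{_GT_CODE[rec.genotype]}\n"
            )
    _ = svlen  # lengths embedded in INFO


def write_report(report, path: str | Path) -> None:
    """Write an EvalReport as a TSV table plus a lossless JSON mirror.

    ``path`` is the TSV destination; a sibling ``.json`` file is written
    alongside. Round-tripping through :func:`read_report` reproduces the
    tabular values exactly.
    """
    path = Path(path)
    df = report.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    payload = {
        "rows": json.loads(df.to_json(orient="records")),
        "extra": report.extra_metrics(),
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1))


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back the TSV table written by :func:`write_report`."""
    return pd.read_csv(Path(path), sep="\t", na_values=["NA"])
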