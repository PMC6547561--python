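"""Synthetic SV truth data and mock caller outputs.

The simulator emulates the statistical structure the evaluation assumes,
at desk scale and at the call-set level: a diploid genome derived from a
(random or supplied) reference by injecting non-overlapping DEL/DUP/INS/INV
variants with ~67% heterozygosity plus background SNVs and short indels,
insertion libraries for the MEI/NUMT/VEI insertion classes, mock callers
that degrade the truth with controlled false-positive/false-negative
rates, breakpoint/length jitter, genotype errors and class-dependent
supporting-read (RSS) distributions, and Mendelian-consistent trios with a
controlled rate of child-only calls.

Read-level simulation is deliberately out of scope: the benchmark operates
on call sets, so reads would add cost without exercising any evaluated
computation.

Everything is deterministic under a fixed seed: identical seeds give
byte-identical genomes, truth sets, and call sets.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from svbench.io_calls import CallSet, ReferenceSet
from svbench.sv_model import SVModelError, SVRecord, SVType

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

#: Per-type SV counts introduced into the full-genome simulated dataset;
#: used as default proportions when scaling to smaller genomes.
SIM_A_COUNTS = {SVType.DEL: 3526, SVType.DUP: 1656, SVType.INS: 2819, SVType.INV: 309}
_SIM_A_TOTAL = sum(SIM_A_COUNTS.values())
_SIM_A_GENOME = 2_880_000_000  # autosomal + X reference size the counts refer to

#: Default per-type SV size ranges in bp (log-uniform sampling).
DEFAULT_SIZE_RANGES = {
    SVType.DEL: (50, 1_000_000),
    SVType.DUP: (100, 1_000_000),
    SVType.INS: (50, 10_000),
    SVType.INV: (50, 1_000_000),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Truth-simulation parameters.

    ``genome_length``/``gc`` shape the random reference (ignored when a
    genome is supplied). SV counts default to the full-genome per-type
    composition scaled to the genome size; ``total_svs`` or explicit
    ``counts`` override. ``het_fraction`` (default 0.67), ``snv_rate``
    (0.001/bp) and ``indel_rate`` (0.0002/bp) follow the simulated-genome
    design the evaluation targets.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 1
    gc: float = 0.41
    counts: Optional[dict] = None
    total_svs: Optional[int] = None
    size_ranges: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_RANGES))
    het_fraction: float = 0.67
    snv_rate: float = 0.001
    indel_rate: float = 0.0002
    placement_margin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_fraction <= 1.0:
            raise SVModelError("het_fraction must lie in [0, 1]")
        if self.counts is not None and any(v < 0 for v in self.counts.values()):
            raise SVModelError("SV counts must be non-negative")

    def resolve_counts(self, genome_length: int) -> dict:
        if self.counts is not None:
            return {t: int(self.counts.get(t, 0)) for t in SVType}
        if self.total_svs is not None:
            total = self.total_svs
        else:
            total = max(4, round(_SIM_A_TOTAL * genome_length / _SIM_A_GENOME))
        return {
            t: max(1, round(total * SIM_A_COUNTS[t] / _SIM_A_TOTAL)) for t in SVType
        }


@dataclass
class MockCallerProfile:
    """Degradation model for a simulated caller.

    ``fp_rate`` is the fraction of *emitted* calls that are novel (match no
    truth variant); ``fn_rate`` the fraction of truth omitted. Breakpoints
    and insertion lengths receive Gaussian jitter; genotypes flip
    (hom <-> het) at ``gt_error_rate``. RSS values are Poisson with a higher
    mean for true calls than for false ones, so RSS filtering trades recall
    for precision the way real callers do.
    """

    fp_rate: float = 0.0
    fn_rate: float = 0.0
    bp_jitter_sd: float = 0.0
    length_jitter_sd: float = 0.0
    gt_error_rate: float = 0.0
    rss_true_mean: float = 15.0
    rss_false_mean: float = 4.0
    method_class: Optional[str] = None
    source_id: str = "mock"

    def __post_init__(self) -> None:
        for r in (self.fp_rate, self.fn_rate, self.gt_error_rate):
            if not 0.0 <= r <= 1.0:
                raise SVModelError("rates must lie in [0, 1]")
        if self.bp_jitter_sd < 0 or self.length_jitter_sd < 0:
            raise SVModelError("jitter SDs must be >= 0")


# ---------------------------------------------------------------------------
# genome generation and FASTA helpers


def generate_genome(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> dict:
    """Seeded random genome as {chrom: sequence}; reproducible per seed."""
    if cfg.genome_length < 10_000:
        raise SVModelError("genome length must be >= 10 kb")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p_gc = cfg.gc / 2.0
    p_at = (1.0 - cfg.gc) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    per = cfg.genome_length // cfg.n_chroms
    return {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=per, p=probs))
        for i in range(cfg.n_chroms)
    }


def read_fasta(path: str | Path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# insertion libraries


@dataclass
class LibraryEntry:
    seq: str
    ins_class: str  # MEI / NUMT / VEI
    source: str
    sub_rate: float = 0.0
    n_subs: int = 0


_BUNDLED = {
    "MEI": "mei_elements_synthetic.fa",
    "NUMT": "mito_like_synthetic.fa",
    "VEI": "virus_like_synthetic.fa",
}


def load_bundled_elements(ins_class: str) -> dict:
    """Bundled synthetic element FASTA (Alu/LINE-like, mito-like, virus-like)."""
    ref = resources.files("svbench") / "data" / _BUNDLED[ins_class]
    with resources.as_file(ref) as p:
        return read_fasta(p)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        for i in np.nonzero(hit)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr), n


def build_insertion_library(
    elements: Optional[dict],
    ins_class: str,
    n: int,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    vei_frag_range: tuple[int, int] = (500, 10_000),
    vei_sub_range: tuple[float, float] = (0.0, 0.05),
    numt_min: int = 100,
    numt_max: int = 5_000,
) -> list[LibraryEntry]:
    """Sample ``n`` insertion sequences of one class from element FASTAs.

    MEI entries are whole element copies. NUMT entries are mito fragments
    with a 100 bp length floor. VEI entries are 500 bp – 10 kb fragments of
    randomly chosen regions, diversified by random substitutions at a
    per-fragment rate drawn uniformly from 0–5%; elements shorter than the
    requested fragment are resampled.
    """
    if ins_class not in _BUNDLED:
        raise SVModelError(f"unknown insertion class {ins_class!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if elements is None:
        elements = load_bundled_elements(ins_class)
    if not elements:
        raise SVModelError("empty element set")
    names = sorted(elements)
    out: list[LibraryEntry] = []
    for _ in range(n):
        if ins_class == "MEI":
            name = names[rng.integers(len(names))]
            out.append(LibraryEntry(elements[name], "MEI", name))
        elif ins_class == "NUMT":
            name = names[rng.integers(len(names))]
            src = elements[name]
            hi = min(numt_max, len(src))
            if hi < numt_min:
                raise SVModelError("mitochondrial element shorter than 100 bp floor")
            ln = int(np.exp(rng.uniform(np.log(numt_min), np.log(hi))))
            start = int(rng.integers(0, len(src) - ln + 1))
            out.append(LibraryEntry(src[start : start + ln], "NUMT", name))
        else:  # VEI
            for _try in range(1000):
                name = names[rng.integers(len(names))]
                src = elements[name]
                ln = int(rng.integers(vei_frag_range[0], vei_frag_range[1] + 1))
                if ln <= len(src):
                    break
            else:
                raise SVModelError("no viral element long enough for fragment")
            start = int(rng.integers(0, len(src) - ln + 1))
            frag = src[start : start + ln]
            rate = float(rng.uniform(*vei_sub_range))
            seq, n_subs = _substitute(frag, rate, rng)
            out.append(LibraryEntry(seq, "VEI", name, rate, n_subs))
    return out


# ---------------------------------------------------------------------------
# truth set


@dataclass
class TruthVariant:
    """One injected variant with its haplotype assignment.

    ``kind`` is an SV type name or one of SNV / SINS / SDEL for the
    background small variants. ``start``/``end`` are reference-footprint
    coordinates (0-based half-open; insertions are zero-width at
    ``start``). ``haps`` flags presence on (haplotype1, haplotype2).
    """

    chrom: str
    start: int
    end: int
    kind: str
    seq: str = ""  # inserted sequence (INS/SINS) or alt base (SNV)
    haps: tuple[bool, bool] = (True, True)
    ins_class: str = "unspecified"

    @property
    def genotype(self) -> str:
        return "hom" if all(self.haps) else "het"

    @property
    def sv_length(self) -> int:
        return len(self.seq) if self.kind in ("INS", "SINS") else self.end - self.start


@dataclass
class TruthSet:
    reference: dict
    variants: list[TruthVariant]

    @property
    def sv_variants(self) -> list[TruthVariant]:
        return [v for v in self.variants if v.kind in SVType.__members__]

    def to_reference_set(self, source_id: str = "truth") -> ReferenceSet:
        recs = []
        for v in self.sv_variants:
            svtype = SVType[v.kind]
            end = v.start + 1 if svtype is SVType.INS else v.end
            recs.append(
                SVRecord(v.chrom, v.start, end, svtype, v.sv_length,
                         genotype=v.genotype, ins_class=v.ins_class)
            )
        return ReferenceSet(recs, source_id=source_id)

    def haplotypes(self) -> tuple[dict, dict]:
        """Apply the recorded edits to the reference, per haplotype."""
        out = []
        for h in (0, 1):
            genome = {}
            for chrom, seq in self.reference.items():
                edits = sorted(
                    (v for v in self.variants if v.chrom == chrom and v.haps[h]),
                    key=lambda v: (v.start, v.end),
                )
                parts = []
                cursor = 0
                for v in edits:
                    parts.append(seq[cursor : v.start])
                    if v.kind in ("INS", "SINS"):
                        parts.append(v.seq)
                        cursor = v.start
                    elif v.kind in ("DEL", "SDEL"):
                        cursor = v.end
                    elif v.kind == "DUP":
                        parts.append(seq[v.start : v.end] * 2)
                        cursor = v.end
                    elif v.kind == "INV":
                        parts.append(revcomp(seq[v.start : v.end]))
                        cursor = v.end
                    elif v.kind == "SNV":
                        parts.append(v.seq)
                        cursor = v.start + 1
                    else:  # pragma: no cover
                        raise SVModelError(f"unknown edit kind {v.kind}")
                parts.append(seq[cursor:])
                genome[chrom] = "".join(parts)
            out.append(genome)
        return out[0], out[1]

    def write_vcf(self, path: str | Path) -> None:
        """Phased truth VCF; replaying it reproduces the haplotypes exactly."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##source=svbench-simulate\n")
            for chrom, seq in self.reference.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
            for line in (
                '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
                '##INFO=<ID=SVEND,Number=1,Type=Integer,Description="0-based exclusive footprint end">',
                '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">',
                '##INFO=<ID=KIND,Number=1,Type=String,Description="Edit kind">',
                '##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted/alt sequence">',
                '##INFO=<ID=INSCLASS,Number=1,Type=String,Description="Insertion class">',
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">',
            ):
                fh.write(line + "\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
            for v in sorted(self.variants, key=lambda v: (v.chrom, v.start, v.end)):
                gt = f"{int(v.haps[0])}|{int(v.haps[1])}"
                info = [f"KIND={v.kind}", f"SVEND={v.end}", f"SVLEN={v.sv_length}"]
                if v.kind in SVType.__members__:
                    info.insert(0, f"SVTYPE={v.kind}")
                if v.seq:
                    info.append(f"SEQ={v.seq}")
                if v.ins_class != "unspecified":
                    info.append(f"INSCLASS={v.ins_class}")
                fh.write(
                    f"{v.chrom}\t{v.start + 1}\t.\tN\t<{v.kind}>\t.\tPASS\t"
                    f"{';'.join(info)}\tGT\t{gt}\n"
                )

    @classmethod
    def read_vcf(cls, path: str | Path, reference: dict) -> "TruthSet":
        import pysam

        variants = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vf = pysam.VariantFile(str(path))
        for rec in vf:
            info = rec.info
            kind = str(info["KIND"])
            end = int(info["SVEND"])
            seq = str(info.get("SEQ", "") or "")
            ins_class = str(info.get("INSCLASS", "unspecified") or "unspecified")
            gt = rec.samples[0]["GT"]
            variants.append(
                TruthVariant(rec.chrom, rec.start, end, kind, seq,
                             (bool(gt[0]), bool(gt[1])), ins_class)
            )
        vf.close()
        return cls(reference, variants)


# ---------------------------------------------------------------------------
# SV injection


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


class _Placer:
    """Non-overlapping placement with a margin, by rejection sampling."""

    def __init__(self, genome: dict, margin: int):
        self.genome = genome
        self.margin = margin
        self.occupied = {c: IntervalTree() for c in genome}
        self.chroms = sorted(genome)
        lens = np.array([len(genome[c]) for c in self.chroms], dtype=float)
        self.weights = lens / lens.sum()

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].addi(start - self.margin, end + self.margin)

    def place(self, span: int, rng: np.random.Generator,
              max_tries: int = 200) -> tuple[str, int]:
        for _ in range(max_tries):
            chrom = self.chroms[rng.choice(len(self.chroms), p=self.weights)]
            limit = len(self.genome[chrom]) - span - self.margin
            if limit <= self.margin:
                continue
            start = int(rng.integers(self.margin, limit))
            if not self.occupied[chrom].overlap(start, start + max(span, 1)):
                self.reserve(chrom, start, start + max(span, 1))
                return chrom, start
        raise SVModelError(
            f"could not place a {span} bp variant without overlap; "
            "genome too small for the requested SV load"
        )


def _draw_haps(rng: np.random.Generator, het_fraction: float) -> tuple[bool, bool]:
    if rng.random() < het_fraction:
        return (True, False) if rng.random() < 0.5 else (False, True)
    return (True, True)


def inject_svs(
    genome: dict,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    insertion_library: Optional[Sequence[LibraryEntry]] = None,
) -> TruthSet:
    """Introduce non-overlapping SVs (plus background SNVs/short indels)
    into a diploid genome and return the truth.

    Each SV is homozygous (both haplotypes) or heterozygous (one haplotype,
    chosen by fair coin) according to ``het_fraction``. DELs remove
    sequence, DUPs tandem-duplicate, INVs reverse-complement, INSs insert
    library or random sequence. Truth coordinates are reference-genome
    coordinates; :meth:`TruthSet.haplotypes` replays the recorded edits,
    and the replay is byte-identical whether driven from memory or from the
    written truth VCF.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genome_length = sum(len(s) for s in genome.values())
    counts = cfg.resolve_counts(genome_length)

    lib = list(insertion_library) if insertion_library else []
    lib_idx = 0

    sizes: list[tuple[SVType, int, Optional[LibraryEntry]]] = []
    for svtype in SVType:
        lo, hi = cfg.size_ranges.get(svtype, DEFAULT_SIZE_RANGES[svtype])
        for _ in range(counts[svtype]):
            entry = None
            if svtype is SVType.INS and lib_idx < len(lib):
                entry = lib[lib_idx]
                lib_idx += 1
                ln = len(entry.seq)
            else:
                ln = _log_uniform(rng, lo, hi)
            sizes.append((svtype, ln, entry))
    budget = sum(ln for t, ln, _ in sizes if t is not SVType.INS)
    if budget * 1.5 + 2 * cfg.placement_margin * len(sizes) > genome_length:
        raise SVModelError(
            f"genome ({genome_length} bp) too small for requested SV load "
            f"({budget} bp of non-INS footprint)"
        )

    placer = _Placer(genome, cfg.placement_margin)
    variants: list[TruthVariant] = []
    # place the largest footprints first so rejection sampling stays cheap
    for svtype, ln, entry in sorted(sizes, key=lambda s: -s[1] * (s[0] is not SVType.INS)):
        span = 0 if svtype is SVType.INS else ln
        chrom, start = placer.place(span, rng)
        haps = _draw_haps(rng, cfg.het_fraction)
        if svtype is SVType.INS:
            if entry is not None:
                seq, ins_class = entry.seq, entry.ins_class
            else:
                seq = "".join(rng.choice(_BASES, size=ln))
                ins_class = "unspecified"
            variants.append(
                TruthVariant(chrom, start, start, "INS", seq, haps, ins_class)
            )
        else:
            variants.append(TruthVariant(chrom, start, start + ln, svtype.value, "",
                                         haps))

    # background small variants outside SV footprints
    n_snv = round(cfg.snv_rate * genome_length)
    n_indel = round(cfg.indel_rate * genome_length)
    for i in range(n_snv + n_indel):
        is_snv = i < n_snv
        ln = 1 if is_snv else int(rng.integers(1, 11))
        try:
            chrom, start = placer.place(ln, rng)
        except SVModelError:
            warnings.warn("ran out of space for background small variants")
            break
        haps = _draw_haps(rng, cfg.het_fraction)
        if is_snv:
            ref_base = genome[chrom][start]
            alts = [b for b in "ACGT" if b != ref_base]
            variants.append(
                TruthVariant(chrom, start, start + 1, "SNV",
                             alts[rng.integers(3)], haps)
            )
        elif rng.random() < 0.5:
            seq = "".join(rng.choice(_BASES, size=ln))
            variants.append(TruthVariant(chrom, start, start, "SINS", seq, haps))
        else:
            variants.append(TruthVariant(chrom, start, start + ln, "SDEL", "", haps))

    return TruthSet(genome, variants)


# ---------------------------------------------------------------------------
# mock callers and trios


def _novel_records(
    truth: TruthSet,
    n: int,
    rng: np.random.Generator,
    clearance: int = 300,
    type_weights: Optional[dict] = None,
) -> list[SVRecord]:
    """Novel SVs guaranteed not to match any truth variant (used for
    false-positive and child-only call injection)."""
    placer = _Placer(truth.reference, clearance)
    for v in truth.sv_variants:
        placer.reserve(v.chrom, v.start, max(v.end, v.start + 1))
    sv_lengths: dict[SVType, list[int]] = {t: [] for t in SVType}
    for v in truth.sv_variants:
        sv_lengths[SVType[v.kind]].append(v.sv_length)
    types = [t for t in SVType if sv_lengths[t]] or list(SVType)
    if type_weights is None:
        w = np.array([max(len(sv_lengths[t]), 1) for t in types], dtype=float)
    else:
        w = np.array([type_weights.get(t, 0.0) for t in types], dtype=float)
    w = w / w.sum()
    out = []
    for _ in range(n):
        svtype = types[rng.choice(len(types), p=w)]
        pool = sv_lengths[svtype] or [1000]
        ln = max(50, int(pool[rng.integers(len(pool))] * rng.uniform(0.5, 2.0)))
        span = 0 if svtype is SVType.INS else ln
        # dense genomes may not fit the drawn size; shrink before giving up
        while True:
            try:
                chrom, start = placer.place(span, rng)
                break
            except SVModelError:
                if ln <= 100:
                    raise
                ln = max(50, ln // 2)
                span = 0 if svtype is SVType.INS else ln
        end = start + 1 if svtype is SVType.INS else start + ln
        gt = "het" if rng.random() < 0.5 else "hom"
        out.append(SVRecord(chrom, start, end, svtype, ln, genotype=gt))
    return out


def _jitter(value: float, sd: float, rng: np.random.Generator) -> int:
    return int(round(value + rng.normal(0.0, sd))) if sd > 0 else int(value)


def mock_caller(
    truth: TruthSet,
    profile: MockCallerProfile,
    seed: int = 0,
) -> CallSet:
    """Emit a degraded call set from the truth under the given profile."""
    rng = np.random.default_rng(seed)
    truth_recs = truth.to_reference_set().records
    if not truth_recs and profile.fp_rate >= 1.0:
        raise SVModelError("fp_rate = 1 with empty truth is unsatisfiable")

    calls: list[SVRecord] = []
    for rec in truth_recs:
        if rng.random() < profile.fn_rate:
            continue
        gt = rec.genotype
        if gt in ("hom", "het") and rng.random() < profile.gt_error_rate:
            gt = "het" if gt == "hom" else "hom"
        rss = 1 + int(rng.poisson(max(profile.rss_true_mean - 1, 0)))
        if rec.svtype is SVType.INS:
            start = _jitter(rec.start, profile.bp_jitter_sd, rng)
            length = rec.length
            if length is not None and profile.length_jitter_sd > 0:
                length = max(1, _jitter(length, profile.length_jitter_sd, rng))
            calls.append(
                SVRecord(rec.chrom, max(start, 0), max(start, 0) + 1, SVType.INS,
                         length, genotype=gt, rss=rss, ins_class=rec.ins_class)
            )
        else:
            start = max(_jitter(rec.start, profile.bp_jitter_sd, rng), 0)
            end = _jitter(rec.end, profile.bp_jitter_sd, rng)
            if end <= start:
                end = start + 1
            calls.append(
                SVRecord(rec.chrom, start, end, rec.svtype, end - start,
                         genotype=gt, rss=rss)
            )

    if profile.fp_rate > 0:
        n_fp = round(len(calls) * profile.fp_rate / (1.0 - profile.fp_rate))
        for rec in _novel_records(truth, n_fp, rng):
            rec.rss = 1 + int(rng.poisson(max(profile.rss_false_mean - 1, 0)))
            calls.append(rec)

    return CallSet(calls, source_id=profile.source_id,
                   method_class=profile.method_class)


def emit_trio(
    truth: TruthSet,
    novel_rate: float,
    seed: int = 0,
    parent_probs: tuple[float, float, float] = (0.5, 0.25, 0.25),
) -> tuple[CallSet, CallSet, CallSet]:
    """Mendelian-consistent trio call sets plus controlled child-only calls.

    Every truth variant is assigned to both parents or to one of them
    (``parent_probs`` = P(both), P(father only), P(mother only)); the child
    carries all truth variants, so each inherited child call matches at
    least one parent. A ``novel_rate`` fraction of the child's calls are
    then injected child-only variants, which constitute the expected
    Mendelian-error fraction.
    """
    if not 0.0 <= novel_rate < 1.0:
        raise SVModelError("novel_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    base = truth.to_reference_set().records
    father, mother, child = [], [], []
    for rec in base:
        u = rng.random()
        in_f = u < parent_probs[0] + parent_probs[1]
        in_m = u < parent_probs[0] or u >= parent_probs[0] + parent_probs[1]
        if in_f:
            father.append(dataclasses.replace(rec))
        if in_m:
            mother.append(dataclasses.replace(rec))
        child.append(dataclasses.replace(rec))
    # fresh ids for the copies
    for group in (father, mother, child):
        for i, rec in enumerate(group):
            group[i] = SVRecord(rec.chrom, rec.start, rec.end, rec.svtype,
                                rec.length, rec.genotype, rec.rss, rec.ins_class)
    n_novel = round(len(child) * novel_rate / (1.0 - novel_rate)) if novel_rate else 0
    child.extend(_novel_records(truth, n_novel, rng))
    return (
        CallSet(child, source_id="child"),
        CallSet(father, source_id="father"),
        CallSet(mother, source_id="mother"),
    )
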