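import numpy as np
import pytest

from svbench.io_calls import CallSet, ReferenceSet
from svbench.simulate import SimConfig, generate_genome, inject_svs
from svbench.sv_model import SVRecord, SVType


def make_rec(chrom="chr1", start=0, end=100, svtype=SVType.DEL, **kw) -> SVRecord:
    return SVRecord(chrom, start, end, svtype, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_del_set(
    rng, n=100, chrom_len=10_000_000, max_len=5_000, source="rand"
) -> CallSet:
    """Random DEL records with random RSS, possibly overlapping."""
    starts = rng.integers(0, chrom_len - max_len, size=n)
    lens = rng.integers(50, max_len, size=n)
    recs = [
        SVRecord("chr1", int(s), int(s + l), SVType.DEL, rss=int(r))
        for s, l, r in zip(starts, lens, rng.integers(0, 21, size=n))
    ]
    return CallSet(recs, source_id=source)


def spaced_reference(rng, n=100, spacing=20_000, min_len=500, max_len=5_000,
                     svtype=SVType.DEL, source="truth") -> ReferenceSet:
    """Well-separated same-type records: no two can match the same call."""
    recs = []
    pos = 1_000
    for _ in range(n):
        ln = int(rng.integers(min_len, max_len))
        recs.append(SVRecord("chr1", pos, pos + ln, svtype,
                             genotype="het" if rng.random() < 0.5 else "hom"))
        pos += ln + spacing
    return ReferenceSet(recs, source_id=source)


@pytest.fixture(scope="session")
def small_truth():
    """A modest injected truth set shared by evaluator-level tests."""
    cfg = SimConfig(
        genome_length=4_000_000,
        n_chroms=2,
        seed=7,
        counts={SVType.DEL: 60, SVType.DUP: 25, SVType.INS: 45, SVType.INV: 10},
        size_ranges={
            SVType.DEL: (1_000, 20_000),
            SVType.DUP: (1_000, 20_000),
            SVType.INV: (1_000, 20_000),
            SVType.INS: (100, 5_000),
        },
        snv_rate=0.0001,
        indel_rate=0.00002,
    )
    genome = generate_genome(cfg)
    return inject_svs(genome, cfg)
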