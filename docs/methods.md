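# Methods

This note documents the models, conventions and design choices behind
`svbench`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open decisions were made.

## Coordinates and the SV model

All internal coordinates are 0-based half-open; VCF input/output converts
from/to 1-based at the boundary, and nowhere else. Four SV types are
modeled — DEL, DUP, INS, INV. Breakends/translocations are outside the
model: normalization drops them (counted, never silent), and CNV records
are expanded into one DEL plus one DUP over the same interval, since depth
evidence alone cannot distinguish the two.

Insertions are stored as 1 bp anchors with an independent (possibly
unknown) length, because callers disagree on the END semantics of INS
records. Non-INS records outside [50 bp, 1 Mb] are excluded at
normalization with a logged count; this is the evaluated size range.

Size classes: DEL-SS 50–100 bp, DEL-S/DUP-S 100 bp–1 kb, DEL-M/DUP-M
1–100 kb, DEL-L/DUP-L 100 kb–1 Mb. The source convention writes the bins
as "50–100 bp" etc. without stating edge inclusivity; we use
lower-inclusive/upper-exclusive edges, with the final 1 Mb bound inclusive
so that variants of exactly 1 Mb remain binned. All threshold comparisons
are ≥ / ≤.

## Truth matching

A call validates a reference variant when:

| type | simulated mode | real mode |
|---|---|---|
| DEL/DUP/INV | reciprocal overlap ≥ 0.8 (0.6 if reference ≤ 1 kb) | ≥ 0.5 |
| INS | insertion points ≤ 200 bp apart | same |

Whether the ≤ 1 kb relaxation keys on the call's or the reference's length
is underdetermined; we key on the reference (the relaxation exists because
small reference variants are hard to recover at 80 %, which is a property
of the reference). The optional length-ratio mode additionally requires
call/reference length within [0.5, 2.0]; calls without a defined length
pass this filter, since the mode exists to reward callers that *do* report
lengths, not to punish those that cannot.

Assignment is greedy one-to-one in descending overlap (ascending distance
for INS), with deterministic id-based tie-breaks. One-to-one is the
conservative reading — it structurally prevents TP > Ref — and the test
suite asserts that on ambiguity-free fixtures the greedy count equals the
exhaustive maximum-bipartite-matching optimum; any gap on adversarial
fixtures would surface there.

INS calls left unmatched are retried against DUP references and vice
versa (the two types describe the same event from different evidence).
The retry criterion is the insertion point (or the DUP call's nearest
breakpoint) within the 200 bp INS window of the other type's breakpoint;
the source methodology states the search but not the distance rule, so
this is a documented choice. Each cross-type hit increments both the TP
count and the reference denominator of the call's type, affecting
precision and recall symmetrically.

Stratification: calls are always matched against the full typed reference
set, never a size-restricted slice, because overlap search legitimately
crosses bin edges. A matched call then counts toward precision in its own
size class and toward recall in the matched reference's class; class-wise
TP counts therefore sum exactly to the total (a conservation law the
acceptance tests assert). Cross-type hits enter the per-type totals only,
as they have no size class on both sides.

Breakpoint error is the mean of |start error| and |end error| for
DEL/DUP/INV and the |insertion-point error| for INS; the combination was
unspecified upstream, and this symmetric convention makes the expected
RMSE of Gaussian jitter σ equal to σ·√(1/2 + 1/π) ≈ 0.905 σ for interval
types and exactly σ for INS — both inside the 15 % recovery band the
tests check.

## Metrics

- Pr = 100·TP/Call, Rc = 100·TP/Ref. Zero denominators yield an explicit
  `None` marker, never 0 or 100.
- Modified F-measure: `F = 2·Pr·Rc·Nrc/(Pr + Rc·Nrc) × 0.01`, Nrc = 2.9 /
  4.0 / 2.4 / 2.4 for DEL/DUP/INS/INV. Nrc compensates the real truth
  set's excess of overlapped references, so stratified reports apply it in
  real mode only (Nrc = 1 for simulated truth). The Nrc constants are
  shipped as configuration; their derivation is not recoverable beyond the
  values themselves.
- Combined precision `cPr = Pr_sim·Pr_real/(mPr_sim·mPr_real)`; pairwise
  results are banded by competition rank into top 20 %, 21–50 %, rest
  (ties share the better band).
- CV uses the sample (n−1) SD — the intended use is across 3–4 datasets,
  where the biased estimator would be noticeably off.
- Spearman's r_s uses the closed form `1 − 6Σd²/(n³−n)`, which assumes
  tie-free ranks; tied inputs raise, directing the caller to pre-rank with
  an explicit tie rule rather than silently approximating.
- RSS selection: the least-stringent threshold whose call count is ≤ 90 %
  of the expected per-type count (DEL 3500, DUP 550, INS 3000, INV 100);
  the optimal RSS maximizes Pr + Rc with ties toward smaller RSS (higher
  recall). The ensemble's "test RSS" defaults to optimal − 2, floored at
  the minimum observed value.
- MIER: a child call is an error when no same-type call in either parent
  reaches 50 % reciprocal overlap (200 bp for INS); MIER is the error
  percentage of all child calls. De novo variants are rare enough that the
  construction treats child-only calls as errors outright.

## RSS extraction

Supporting-read counts are caller-specific; the reader implements a rule
framework rather than per-tool constants: sum of the named support fields
(default PE + SR + RSS, missing fields contributing 0 with a warning), a
single named field, or a 10-level quantile rank of a score for callers
reporting only depth or quality statistics. The quantile rank uses
max-method ranks mapped through ceil(levels·rank/n): monotone in the score
and invariant under monotone rescaling.

## Truth-set construction

Pipeline order: per-source short-variant removal (DELs and INSs < 1 kb or
with unknown length, applied to designated lower-confidence sources) →
cross-source dedup (≥ 95 % reciprocal overlap, 90 % for > 1 kb, within
DEL/DUP/INV only) → merge keeping the longer record (≥ 70 %, cross-source
pairs only; equal lengths keep the higher-priority source) → final
min-size filter (non-INS < 50 bp; a 30 bp profile exists for truth sets
defined down to 30 bp). Sources are processed pairwise in priority order;
the pairing order for three-way overlaps is itself a convention and is
documented as such.

The final set is deliberately *not* forced to be non-redundant: overlaps
below the dedup thresholds cannot be adjudicated without external
evidence, so they are kept and their count reported in the merge audit.

## Simulator

The simulator generates truth *call sets*, not reads: the evaluation
operates entirely on call sets, so read simulation and alignment would add
cost without exercising any computation under test.

`inject_svs` places non-overlapping SVs (20 bp margin) on a random or
supplied reference and assigns each to both haplotypes (hom) or one (het,
fair coin) with heterozygous fraction 0.67 by default. Defaults follow
the full-genome simulated-truth design: per-type composition
3526/1656/2819/309 (DEL/DUP/INS/INV, scaled to the genome), SNVs at 0.1 %
and short indels at 0.02 % of genome size. Sizes are log-uniform within a
configurable per-type range defaulting to [50 bp, 1 Mb] (DUP from 100 bp,
INS up to 10 kb); the upstream size distributions derive from database
records that are not printed, so log-uniform is a declared stand-in, not a
claimed match. Truth coordinates are reference coordinates; haplotype
construction replays the recorded edits left to right, and the truth VCF
(phased GT, inserted sequences inline) round-trips to byte-identical
haplotype FASTAs — the strongest available check on the injection
arithmetic.

Insertion classes: MEI entries are whole element copies; NUMT entries are
mitochondrial fragments with a 100 bp floor; VEI entries are 500 bp–10 kb
fragments of viral sequence diversified by per-fragment substitution rates
drawn uniformly from 0–5 %. Small synthetic element libraries (Alu-like,
LINE-like, mito-like, virus-like random sequences, labeled synthetic) ship
in-repo so these paths need no downloads; they reproduce the length and
divergence structure of the real libraries, not their sequence content.

`mock_caller` emits the truth minus a binomial `fn_rate` fraction, with
Gaussian breakpoint/length jitter, hom↔het flips at `gt_error_rate`, and
novel false calls placed ≥ 300 bp clear of any truth variant so they can
never match; RSS is Poisson with a higher mean for true calls (15 vs 4 by
default), reproducing the precision/recall trade-off that RSS filtering
exploits. `emit_trio` assigns every truth variant to both parents or one
(0.5/0.25/0.25), gives the child all of them plus a `novel_rate` fraction
of child-only calls, making the expected MIER exactly the novel fraction.

All operations are deterministic under a fixed seed.

### What the simulator does and does not emulate

It reproduces the statistical structure the evaluator consumes — error
rates, jitter, support distributions, heterozygosity, Mendelian structure
— but not alignment artifacts, reference bias, repeat-context effects, or
correlated errors between callers sharing a signal type. Passing tests
therefore validate the *evaluation machinery* (matching, stratification,
statistics) and the simulator's own contracts; they do not certify any
real caller's accuracy.

## Problem sizes and numerics

The test suite runs the identity check at 10,000 SVs, parameter recovery
at 2,000 truth SVs × 10 seeds (SVs of 1–10 kb, so 20 bp jitter cannot
erode reciprocal overlap below threshold and confound the recovered
rates), trio analysis at 500 SVs × 10 seeds, and oracle equivalence on 200
fixtures of ≤ 200 records; the acceptance script uses a 10 Mb genome with
1,000 SVs. Stochastic assertions use 3-binomial-SD bands; exact formula
checks use 1e-4 or tighter. Degenerate inputs (zero-length records,
tied ranks, zero denominators, infeasible SV loads) raise or return
explicit markers rather than guessing.

## Known limitations

- Per-caller RSS conversion constants for specific published tools are
  intentionally out of scope; only the rule framework is provided.
- Multi-sample VCFs are rejected rather than interpreted.
- Iterated pairwise merging is the only consensus mechanism; no k-wise
  (k > 2) consensus model.
- The greedy matcher is exact on unambiguous inputs but may in principle
  fall below the optimal matching on densely overlapping call sets; the
  oracle test bounds this in practice.
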