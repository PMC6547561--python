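import numpy as np
import pytest
import scipy.stats

from svbench.evaluator import (
    EvalConfig,
    coefficient_of_variation,
    combined_precision,
    f_measure,
    genotype_concordance,
    match_calls,
    mendelian_error_rate,
    normalized_f,
    precision_recall,
    rmse,
    select_optimal_rss,
    select_rss,
    spearman_rank,
    stratified_eval,
    sweep_rss,
)
from svbench.io_calls import CallSet, ReferenceSet
from svbench.sv_model import MatchCriteria, SVModelError, SVRecord, SVType
from tests.conftest import make_rec, random_del_set, spaced_reference


def _sets(calls, refs):
    return CallSet(calls, source_id="calls"), ReferenceSet(refs, source_id="truth")


class TestMatchCalls:
    def test_simulated_80pct_rule(self):
        # 85% reciprocal with a 5 kb reference: TP in simulated mode
        calls, ref = _sets([make_rec(start=0, end=5000)],
                           [make_rec(start=750, end=5750)])  # ovl 4250/5000
        m = match_calls(calls, ref, EvalConfig(mode="simulated"))
        assert m.tp_count() == 1

    def test_mode_dependent_threshold(self):
        # 70% reciprocal: FP in simulated mode, TP in real mode
        for mode, expected_tp in (("simulated", 0), ("real", 1)):
            calls, ref = _sets([make_rec(start=0, end=5000)],
                               [make_rec(start=1500, end=6500)])
            m = match_calls(calls, ref, EvalConfig(mode=mode))
            assert m.tp_count() == expected_tp, mode

    def test_small_reference_relaxation(self):
        # 65% reciprocal with an 800 bp reference: the 60% small-variant
        # threshold applies in simulated mode
        calls, ref = _sets([make_rec(start=0, end=800)],
                           [make_rec(start=280, end=1080)])  # ovl 520/800 = 0.65
        m = match_calls(calls, ref, EvalConfig(mode="simulated"))
        assert m.tp_count() == 1

    def test_ins_window_and_length_ratio(self):
        cfg = EvalConfig(mode="simulated")
        cfg.criteria.length_ratio_mode = True
        calls, ref = _sets(
            [make_rec(start=1150, end=1151, svtype=SVType.INS, length=300)],
            [make_rec(start=1000, end=1001, svtype=SVType.INS, length=500)],
        )
        m = match_calls(calls, ref, cfg)  # 150 bp apart, ratio 0.6 in [0.5, 2]
        assert m.tp_count() == 1

    def test_length_ratio_rejects_out_of_band(self):
        cfg = EvalConfig(mode="simulated")
        cfg.criteria.length_ratio_mode = True
        calls, ref = _sets(
            [make_rec(start=1000, end=1001, svtype=SVType.INS, length=100)],
            [make_rec(start=1000, end=1001, svtype=SVType.INS, length=500)],
        )
        assert match_calls(calls, ref, cfg).tp_count() == 0

    def test_unknown_length_passes_length_ratio(self):
        cfg = EvalConfig(mode="simulated")
        cfg.criteria.length_ratio_mode = True
        calls, ref = _sets(
            [make_rec(start=1000, end=1001, svtype=SVType.INS, length=None)],
            [make_rec(start=1000, end=1001, svtype=SVType.INS, length=500)],
        )
        assert match_calls(calls, ref, cfg).tp_count() == 1

    def test_empty_call_set(self):
        calls, ref = _sets([], [make_rec(start=0, end=1000)])
        m = match_calls(calls, ref, EvalConfig())
        assert m.tp_count() == 0 and len(m.fn) == 1

    def test_one_to_one_assignment(self):
        # two identical calls, one reference: only one TP
        calls, ref = _sets(
            [make_rec(start=0, end=1000), make_rec(start=0, end=1000)],
            [make_rec(start=0, end=1000)],
        )
        m = match_calls(calls, ref, EvalConfig())
        assert m.tp_count() == 1 and len(m.fp) == 1

    def test_cross_type_ins_to_dup(self):
        # INS call with no INS reference lands on a DUP reference breakpoint
        calls, ref = _sets(
            [make_rec(start=1000, end=1001, svtype=SVType.INS, length=400)],
            [make_rec(start=950, end=3000, svtype=SVType.DUP)],
        )
        m = match_calls(calls, ref, EvalConfig())
        assert m.tp_count(SVType.INS) == 1
        assert m.cross_type_hits[SVType.INS] == 1
        # the hit is added to both TP and the INS reference denominator
        pr, rc = precision_recall(m, SVType.INS)
        assert pr == 100.0 and rc == 100.0

    def test_cross_type_dup_to_ins_symmetric(self):
        calls, ref = _sets(
            [make_rec(start=950, end=3000, svtype=SVType.DUP)],
            [make_rec(start=1000, end=1001, svtype=SVType.INS, length=400)],
        )
        m = match_calls(calls, ref, EvalConfig())
        assert m.cross_type_hits[SVType.DUP] == 1
        pr, rc = precision_recall(m, SVType.DUP)
        assert pr == 100.0 and rc == 100.0


class TestPrecisionRecall:
    def test_formula(self):
        calls, ref = _sets(
            [make_rec(start=i * 10_000, end=i * 10_000 + 1000) for i in range(4)],
            [make_rec(start=i * 10_000, end=i * 10_000 + 1000) for i in range(2)]
            + [make_rec(start=10**6 + i * 10_000, end=10**6 + i * 10_000 + 1000)
               for i in range(6)],
        )
        m = match_calls(calls, ref, EvalConfig())
        pr, rc = precision_recall(m)
        assert pr == pytest.approx(50.0)  # TP=2, Call=4
        assert rc == pytest.approx(25.0)  # Ref=8

    def test_identity(self, rng):
        ref = spaced_reference(rng, n=50)
        calls = CallSet(ref.records, source_id="same")
        pr, rc = precision_recall(match_calls(calls, ref, EvalConfig()))
        assert (pr, rc) == (100.0, 100.0)

    def test_undefined_markers(self):
        calls, ref = _sets([], [])
        pr, rc = precision_recall(match_calls(calls, ref, EvalConfig()))
        assert pr is None and rc is None


class TestStratifiedEval:
    def test_size_class_precision_vs_recall_attribution(self):
        # a 900 bp DEL call matching a 1.2 kb DEL reference counts toward
        # DEL-S precision but DEL-M recall (real-mode 50% threshold)
        calls, ref = _sets([make_rec(start=100, end=1000)],
                           [make_rec(start=0, end=1200)])
        rep = stratified_eval(calls, ref, EvalConfig(mode="real"))
        assert rep.row("DEL", "DEL-S").tp_call == 1
        assert rep.row("DEL", "DEL-S").precision == 100.0
        assert rep.row("DEL", "DEL-M").tp_ref == 1
        assert rep.row("DEL", "DEL-M").recall == 100.0
        assert rep.row("DEL", "DEL-M").tp_call == 0

    def test_truth_against_itself_all_categories_perfect(self, small_truth):
        ref = small_truth.to_reference_set()
        calls = CallSet(ref.records, source_id="self")
        rep = stratified_eval(calls, ref, EvalConfig(mode="simulated"))
        for row in rep.rows:
            if row.call:
                assert row.precision == 100.0
            if row.ref:
                assert row.recall == 100.0
        assert all(v == 0.0 for v in rep.bp_rmse.values())
        assert all(v == 0.0 for v in rep.length_rmse.values())
        assert rep.genotype[0] == 100.0

    def test_classwise_tp_conservation(self, rng):
        ref = spaced_reference(rng, n=120, min_len=60, max_len=200_000)
        # jittered copies of a subset: still match, may change size class
        calls = CallSet(
            [
                SVRecord("chr1", r.start + int(rng.integers(-5, 6)), r.end,
                         SVType.DEL)
                for r in ref.records[:80]
            ],
            source_id="jit",
        )
        cfg = EvalConfig(mode="real")
        rep = stratified_eval(calls, ref, cfg)
        total = rep.row("DEL", "ALL")
        class_rows = [r for r in rep.rows if r.svtype == "DEL" and r.size_class != "ALL"]
        assert sum(r.tp_call for r in class_rows) == total.tp_call
        assert sum(r.tp_ref for r in class_rows) == total.tp_ref


class TestRssSelection:
    def _sweep_table(self, counts):
        import pandas as pd

        return pd.DataFrame(
            [{"RSS": k, "Call": v, "TP": 0, "Pr": None, "Rc": None}
             for k, v in counts.items()]
        )

    def test_sweep_monotone_and_threshold_zero_identity(self, rng):
        ref = spaced_reference(rng, n=60)
        calls = CallSet(
            [SVRecord(r.chrom, r.start, r.end, r.svtype, rss=int(rng.integers(0, 15)))
             for r in ref.records],
            source_id="c",
        )
        cfg = EvalConfig(mode="simulated")
        table = sweep_rss(calls, ref, cfg, list(range(0, 16)))
        assert table.loc[0, "Call"] == len(calls)
        assert (table["Call"].diff().dropna() <= 0).all()
        rc = table["Rc"].astype(float)
        assert (rc.diff().dropna() <= 1e-9).all()  # recall only falls

    def test_select_rss_cap(self):
        sweep = self._sweep_table({2: 5000, 4: 3100, 6: 2000})
        assert select_rss(sweep, expected=3500, cap_frac=0.9) == 4  # cap 3150

    def test_select_rss_all_under_cap(self):
        sweep = self._sweep_table({1: 100, 3: 50})
        assert select_rss(sweep, expected=3500) == 1

    def test_select_rss_none_under_cap_warns(self):
        sweep = self._sweep_table({1: 9000, 5: 8000})
        with pytest.warns(UserWarning):
            assert select_rss(sweep, expected=3500) == 5

    def test_select_rss_matches_exhaustive_scan(self, rng):
        for _ in range(25):
            counts = {
                int(t): int(c)
                for t, c in zip(range(0, 20), np.sort(rng.integers(0, 6000, 20))[::-1])
            }
            sweep = self._sweep_table(counts)
            cap = 0.9 * 3500
            oracle = [t for t, c in counts.items() if c <= cap]
            if oracle:
                assert select_rss(sweep, 3500) == min(oracle)

    def test_select_optimal_rss(self):
        import pandas as pd

        sweep = pd.DataFrame(
            [{"RSS": 2, "Pr": 60.0, "Rc": 50.0}, {"RSS": 5, "Pr": 80.0, "Rc": 40.0},
             {"RSS": 8, "Pr": 90.0, "Rc": 20.0}]
        )
        assert select_optimal_rss(sweep) == 5

    def test_select_optimal_tie_prefers_smaller(self):
        import pandas as pd

        sweep = pd.DataFrame(
            [{"RSS": 3, "Pr": 60.0, "Rc": 40.0}, {"RSS": 6, "Pr": 70.0, "Rc": 30.0}]
        )
        assert select_optimal_rss(sweep) == 3


class TestFMeasure:
    def test_harmonic_mean_identity(self):
        assert f_measure(100, 100, 1.0) == pytest.approx(1.0)

    def test_published_row_value(self):
        # Pr 87.6, Rc 28.9, Nrc 2.9 (DEL, real data)
        assert f_measure(87.6, 28.9, 2.9) == pytest.approx(0.8566, abs=1e-4)

    def test_zero_recall_gives_zero(self):
        assert f_measure(50.0, 0.0, 2.9) == 0.0

    def test_strictly_increasing_in_both_arguments(self, rng):
        for _ in range(50):
            pr, rc = rng.uniform(1, 99, 2)
            nrc = rng.uniform(0.5, 4)
            base = f_measure(pr, rc, nrc)
            assert f_measure(pr + 1, rc, nrc) > base
            assert f_measure(pr, rc + 1, nrc) > base

    def test_bounded_by_two(self, rng):
        for _ in range(100):
            f = f_measure(*rng.uniform(0.1, 100, 2), rng.uniform(0.1, 10))
            assert 0 <= f <= 2


class TestScalarStats:
    def test_normalized_f(self):
        assert normalized_f({"a": 1.0})["a"] == 1.0
        nf = normalized_f({"a": 1.0, "b": 3.0})
        assert (nf["a"], nf["b"]) == (0.5, 1.5)

    def test_normalized_f_mean_is_one(self, rng):
        vals = {f"alg{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 2, 12))}
        assert np.mean(list(normalized_f(vals).values())) == pytest.approx(1.0)

    def test_combined_precision(self):
        assert combined_precision(50, 30, 50, 30) == pytest.approx(1.0)
        assert combined_precision(90, 30, 45, 15) == pytest.approx(4.0)
        assert combined_precision(90, 30, 0, 15) is None

    def test_cv(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0
        assert coefficient_of_variation([90.0, 110.0]) == pytest.approx(
            np.sqrt(200.0) / 100.0
        )

    def test_cv_scale_invariant(self, rng):
        x = rng.uniform(10, 100, 8)
        assert coefficient_of_variation(7.3 * x) == pytest.approx(
            coefficient_of_variation(x)
        )

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
        ],
    )
    def test_spearman_closed_form(self, a, b, expected):
        assert spearman_rank(a, b) == pytest.approx(expected)

    def test_spearman_rejects_ties(self):
        with pytest.raises(SVModelError):
            spearman_rank([1, 1, 2], [1, 2, 3])

    def test_spearman_matches_scipy_on_permutations(self, rng):
        for n in (5, 10, 30, 50):
            a = rng.permutation(n) + 1
            b = rng.permutation(n) + 1
            expected = scipy.stats.spearmanr(a, b).statistic
            assert spearman_rank(a, b) == pytest.approx(expected)

    def test_rmse(self):
        assert rmse([(5, 5), (9, 9)]) == 0.0
        assert rmse([(int(x) + 10, int(x)) for x in range(7)]) == pytest.approx(10.0)
        assert rmse([(3, 0), (4, 0)]) == pytest.approx(np.sqrt(12.5))
        assert rmse([]) is None


class TestGenotypeConcordance:
    def _match_identity(self, call_gts, ref_gts, n_ref_extra=0):
        refs = [
            make_rec(start=i * 50_000, end=i * 50_000 + 1000, genotype=g)
            for i, g in enumerate(ref_gts)
        ]
        extra = [
            make_rec(start=(100 + i) * 50_000, end=(100 + i) * 50_000 + 1000,
                     genotype="het")
            for i in range(n_ref_extra)
        ]
        calls = [
            make_rec(start=i * 50_000, end=i * 50_000 + 1000, genotype=g)
            for i, g in enumerate(call_gts)
        ]
        cs, ref = _sets(calls, refs + extra)
        m = match_calls(cs, ref, EvalConfig())
        return genotype_concordance(m, cs, ref)

    def test_all_correct(self):
        p1, p2, rc = self._match_identity(["het"] * 5, ["het"] * 5)
        assert p1 == 100.0 and p2 == 100.0 and rc == 100.0

    def test_partial_concordance(self):
        # 10 TP sites, 8 genotyped, 6 correct: P1 = 60, P2 = 75
        call_gts = ["het"] * 6 + ["hom"] * 2 + ["unknown"] * 2
        ref_gts = ["het"] * 10
        p1, p2, rc = self._match_identity(call_gts, ref_gts)
        assert p1 == pytest.approx(60.0)
        assert p2 == pytest.approx(75.0)

    def test_recall_uses_total_reference(self):
        # 6 correct genotypes, 20 genotyped reference sites: recall 30
        p1, p2, rc = self._match_identity(
            ["het"] * 6 + ["hom"] * 4, ["het"] * 10, n_ref_extra=10
        )
        assert rc == pytest.approx(30.0)

    def test_no_genotyped_reference_is_undefined(self):
        assert self._match_identity(["het"], ["unknown"]) is None


class TestMendelianErrorRate:
    def test_all_in_father_zero(self, rng):
        ref = spaced_reference(rng, n=20)
        child = CallSet(ref.records, source_id="child")
        father = CallSet(ref.records, source_id="father")
        mother = CallSet([], source_id="mother")
        assert mendelian_error_rate(child, father, mother) == 0.0

    def test_counting(self, rng):
        ref = spaced_reference(rng, n=10)
        novel = [make_rec(start=5_000_000 + i * 100_000,
                          end=5_000_000 + i * 100_000 + 500) for i in range(2)]
        child = CallSet(ref.records[:8] + novel, source_id="child")
        father = CallSet(ref.records[:5], source_id="father")
        mother = CallSet(ref.records[4:], source_id="mother")
        assert mendelian_error_rate(child, father, mother) == pytest.approx(20.0)

    def test_ins_window_criterion(self):
        c = make_rec(start=1000, end=1001, svtype=SVType.INS, length=100)
        near = make_rec(start=1190, end=1191, svtype=SVType.INS, length=100)
        far = make_rec(start=1300, end=1301, svtype=SVType.INS, length=100)
        child = CallSet([c], source_id="child")
        assert mendelian_error_rate(child, CallSet([near]), CallSet([])) == 0.0
        assert mendelian_error_rate(child, CallSet([far]), CallSet([])) == 100.0

    def test_empty_child_undefined(self):
        assert mendelian_error_rate(CallSet([]), CallSet([]), CallSet([])) is None


class TestGreedyVsOptimalMatching:
    def test_matches_maximum_bipartite_on_ambiguity_free_fixtures(self, rng):
        """On spaced fixtures the greedy TP count equals the optimum."""
        import networkx as nx

        cfg = EvalConfig(mode="real")
        for trial in range(20):
            ref = spaced_reference(rng, n=40)
            # jittered + dropped + extra calls
            calls = []
            for r in ref.records:
                if rng.random() < 0.7:
                    s = r.start + int(rng.integers(-50, 51))
                    calls.append(SVRecord("chr1", s, s + (r.end - r.start),
                                          SVType.DEL))
            cs = CallSet(calls, source_id="c")
            m = match_calls(cs, ref, cfg)

            g = nx.Graph()
            from svbench.sv_model import reciprocal_overlap

            for c in cs:
                for r in ref:
                    if reciprocal_overlap(c, r) >= 0.5:
                        g.add_edge(("c", c.id), ("r", r.id))
            opt = len(nx.algorithms.matching.max_weight_matching(g, maxcardinality=True))
            assert m.tp_count() == opt
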