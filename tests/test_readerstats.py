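"""Reader-study statistics: confusion tables, t-tests, sample size."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from fiberbrush.readerstats import (
    GoldLabel,
    ReaderResponse,
    confusion,
    demo_gold_labels,
    diagnostic_metrics,
    equivalence_sample_size,
    reader_study_report,
    simulate_reader_responses,
    unpaired_t_test,
)


def _toy(truths, calls, confidences=None):
    gold = [GoldLabel(f"i{k}", t) for k, t in enumerate(truths)]
    conf = confidences or ["high"] * len(calls)
    resp = [
        ReaderResponse("r1", f"i{k}", "HR", c, cf)
        for k, (c, cf) in enumerate(zip(calls, conf))
    ]
    return resp, gold


P, N = "neoplastic", "non_neoplastic"


class TestConfusion:
    def test_all_correct_has_no_errors(self):
        resp, gold = _toy([P, P, N, N], [P, P, N, N])
        assert confusion(resp, gold) == (2, 0, 0, 2)

    def test_hand_enumerated_example(self):
        truths = [P] * 4 + [N] * 6
        calls = [P, P, P, N, P, N, N, N, N, N]
        resp, gold = _toy(truths, calls)
        assert confusion(resp, gold) == (3, 1, 1, 5)

    def test_empty_stratum_gives_zero_counts(self):
        resp, gold = _toy([P, N], [P, N], ["high", "high"])
        counts = confusion(resp, gold, stratum="low_conf")
        assert counts == (0, 0, 0, 0)
        summ = diagnostic_metrics(counts, stratum="low_conf")
        assert summ.total == 0 and summ.accuracy is None

    def test_strata_partition_into_all(self, rng):
        truths = [P if rng.random() < 0.6 else N for _ in range(40)]
        calls = [P if rng.random() < 0.5 else N for _ in range(40)]
        confs = ["high" if rng.random() < 0.5 else "low" for _ in range(40)]
        resp, gold = _toy(truths, calls, confs)
        total = np.array(confusion(resp, gold, "all"))
        hi = np.array(confusion(resp, gold, "high_conf"))
        lo = np.array(confusion(resp, gold, "low_conf"))
        assert np.array_equal(total, hi + lo)

    def test_order_invariance(self):
        truths = [P] * 4 + [N] * 6
        calls = [P, P, P, N, P, N, N, N, N, N]
        resp, gold = _toy(truths, calls)
        assert confusion(resp[::-1], gold) == confusion(resp, gold)

    def test_missing_gold_label_lists_ids(self):
        resp, gold = _toy([P, N], [P, N])
        with pytest.raises(ValueError, match="i1"):
            confusion(resp, gold[:1])


class TestDiagnosticMetrics:
    def test_toy_matrix_ratios(self):
        s = diagnostic_metrics((3, 1, 1, 5))
        assert s.sensitivity == pytest.approx(0.75)
        assert s.specificity == pytest.approx(5 / 6)
        assert s.accuracy == pytest.approx(0.8)

    def test_perfect_reader(self):
        s = diagnostic_metrics((7, 0, 0, 3))
        assert s.sensitivity == s.specificity == s.accuracy == 1.0

    def test_zero_denominator_reported_absent(self):
        s = diagnostic_metrics((0, 2, 0, 8))
        assert s.sensitivity is None
        assert s.specificity == pytest.approx(0.8)

    def test_exhaustive_small_tables_match_bruteforce(self):
        # every 2x2 table with total <= 8, reconstructed as explicit
        # response lists and recounted
        for tp, fp, fn, tn in itertools.product(range(9), repeat=4):
            if not 0 < tp + fp + fn + tn <= 8:
                continue
            truths = [P] * (tp + fn) + [N] * (fp + tn)
            calls = [P] * tp + [N] * fn + [P] * fp + [N] * tn
            resp, gold = _toy(truths, calls)
            assert confusion(resp, gold) == (tp, fp, fn, tn)
            s = diagnostic_metrics((tp, fp, fn, tn))
            if tp + fn:
                assert s.sensitivity == tp / (tp + fn)
            if tn + fp:
                assert s.specificity == tn / (tn + fp)
            assert s.accuracy == (tp + tn) / (tp + fp + fn + tn)


class TestUnpairedTTest:
    def test_identical_groups_null(self):
        t, df, p = unpaired_t_test([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_formula_example(self):
        # pooled SD 0.02, diff 0.1, se = 0.02*sqrt(2/3) -> t = 6.1237, df 4
        t, df, p = unpaired_t_test([0.70, 0.72, 0.74], [0.60, 0.62, 0.64])
        assert df == 4
        assert t == pytest.approx(0.1 / (0.02 * math.sqrt(2 / 3)), rel=1e-12)
        assert t == pytest.approx(6.123724, abs=1e-6)

    def test_group_swap_negates_t_preserves_p(self, rng):
        a = list(rng.random(5))
        b = list(rng.random(6))
        t1, _, p1 = unpaired_t_test(a, b)
        t2, _, p2 = unpaired_t_test(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_matches_scipy_on_random_groups(self, rng):
        for _ in range(50):
            a = rng.normal(0.7, 0.1, rng.integers(2, 12))
            b = rng.normal(0.6, 0.15, rng.integers(2, 12))
            t, df, p = unpaired_t_test(list(a), list(b))
            ref = sp_stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            tw, dfw, pw = unpaired_t_test(list(a), list(b), equal_var=False)
            refw = sp_stats.ttest_ind(a, b, equal_var=False)
            assert tw == pytest.approx(refw.statistic, abs=1e-10)
            assert pw == pytest.approx(refw.pvalue, abs=1e-10)

    def test_degenerate_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([0.5, 0.5], [0.7, 0.7])

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([0.5], [0.6, 0.7])


class TestEquivalenceSampleSize:
    def test_direct_formula_evaluation(self):
        # (1.95996 + 0.84162)^2 * 2 * 0.25 / 0.15^2 = 174.4 -> 175
        assert equivalence_sample_size(0.5, 0.15) == 175

    def test_wider_limit_needs_fewer_images(self):
        assert (equivalence_sample_size(0.7, 0.30)
                < equivalence_sample_size(0.7, 0.15))

    def test_halving_limit_quadruples_n_up_to_rounding(self):
        n = equivalence_sample_size(0.7, 0.2)
        n_half = equivalence_sample_size(0.7, 0.1)
        assert 0 <= 4 * n - n_half <= 3

    def test_invalid_parameters_rejected(self):
        for bad in ({"p_assumed": 0.0}, {"limit": 1.0}, {"alpha": 0.0}):
            kwargs = {"p_assumed": 0.5, "limit": 0.15, **bad}
            with pytest.raises(ValueError):
                equivalence_sample_size(**kwargs)


class TestReaderStudyReport:
    def test_identical_hr_sr_tables_give_null_tests(self):
        gold = demo_gold_labels(seed=1)
        readers = ["r1", "r2", "r3", "r4"]
        hr = simulate_reader_responses(gold, readers, accuracy=0.7,
                                       conditions=("HR",), seed=5)
        sr = [
            ReaderResponse(r.reader_id, r.image_id, "SR", r.call,
                           r.confidence)
            for r in hr
        ]
        report = reader_study_report(hr + sr, gold)
        for metric, res in report["t_tests"].items():
            assert res["p"] == pytest.approx(1.0)

    def test_simulated_accuracy_within_binomial_interval(self):
        gold = demo_gold_labels(seed=2)
        readers = ["r1", "r2", "r3", "r4"]
        resp = simulate_reader_responses(gold, readers, accuracy=0.70,
                                         seed=8)
        report = reader_study_report(resp, gold)
        pooled = report["pooled"]
        row = pooled[(pooled.condition == "HR")
                     & (pooled.stratum == "all")].iloc[0]
        n = row.TP + row.FP + row.FN + row.TN
        half = 1.96 * math.sqrt(0.7 * 0.3 / n)
        assert abs(row.accuracy - 0.70) < half

    def test_demo_gold_set_has_published_class_mix(self):
        gold = demo_gold_labels()
        assert len(gold) == 120
        assert sum(g.truth == P for g in gold) == 78
        assert sum(g.truth == N for g in gold) == 42

    def test_single_reader_omits_t_tests_with_notice(self):
        gold = demo_gold_labels(n=10, neoplastic=6, seed=3)
        resp = simulate_reader_responses(gold, ["solo"], seed=4)
        report = reader_study_report(resp, gold)
        assert report["t_tests"] is None
        assert "fewer than two readers" in report["notice"]

    def test_high_confidence_fraction_bounds(self):
        gold = demo_gold_labels(n=20, neoplastic=10, seed=6)
        resp = simulate_reader_responses(gold, ["a", "b"],
                                         high_conf_rate=0.5, seed=7)
        frac = report = reader_study_report(resp, gold)[
            "high_confidence_fraction"
        ]
        for cond in ("HR", "SR"):
            assert 0.0 <= frac[cond] <= 1.0

    def test_missing_condition_rejected(self):
        gold = demo_gold_labels(n=6, neoplastic=3, seed=9)
        resp = simulate_reader_responses(gold, ["r1"], conditions=("HR",),
                                         seed=10)
        with pytest.raises(ValueError):
            reader_study_report(resp, gold)
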