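"""Metric correctness against independent oracles and hand computations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plantarch.metrics import (
    bleu4,
    lcs_length,
    normalized_wasserstein,
    regression_metrics,
    rouge_l,
    token_accuracy,
    wasserstein_1d,
    weighted_f1,
    evaluate_sequences,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def lcs_brute_force(a, b):
    """Maximum length over all common subsequences, by enumeration."""
    best = 0
    for r in range(len(a), 0, -1):
        for sub in itertools.combinations(a, r):
            it = iter(b)
            if all(x in it for x in sub):
                return r
    return best


def wasserstein_lp(a, b):
    """p=1 optimal transport between empirical samples via linear programming."""
    from scipy.optimize import linprog

    n, m = len(a), len(b)
    cost = np.abs(np.subtract.outer(a, b)).ravel()
    a_eq = []
    for i in range(n):
        row = np.zeros((n, m)); row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(m):
        row = np.zeros((n, m)); row[:, j] = 1
        a_eq.append(row.ravel())
    b_eq = np.concatenate([np.full(n, 1 / n), np.full(m, 1 / m)])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, method="highs")
    assert res.success
    return res.fun


class TestLCS:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), max_size=8), st.lists(st.integers(0, 3), max_size=8))
    def test_dp_matches_enumeration(self, a, b):
        assert lcs_length(a, b) == lcs_brute_force(a, b)

    def test_known_values(self):
        assert lcs_length([1, 2, 3, 4], [2, 4]) == 2
        assert lcs_length([1, 2, 3], [4, 5, 6]) == 0
        assert lcs_length([1, 2, 3], [1, 2, 3]) == 3


class TestWasserstein:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=100)
        assert wasserstein_1d(x, x) == 0.0

    def test_point_masses_closed_form(self):
        assert wasserstein_1d([2.0], [5.0]) == pytest.approx(3.0)

    @pytest.mark.parametrize("sizes", [(50, 50), (30, 50), (7, 13)])
    def test_matches_lp_transport(self, sizes, rng):
        a = rng.normal(0, 1, size=sizes[0])
        b = rng.normal(0.5, 2, size=sizes[1])
        assert wasserstein_1d(a, b) == pytest.approx(wasserstein_lp(a, b), abs=1e-9)

    def test_quantile_integration_agrees_with_cdf_form_at_p1(self, rng):
        # the general-p quantile integration evaluated at p=1 must reproduce
        # the integrated-CDF-difference computation
        from plantarch.metrics import _quantile_wasserstein

        a = rng.uniform(size=40)
        b = rng.uniform(size=60)
        assert _quantile_wasserstein(np.sort(a), np.sort(b), 1.0) == pytest.approx(
            wasserstein_1d(a, b), abs=1e-12)

    def test_p2_on_shifted_point_masses(self):
        # W_2 between unit point masses = |a-b|
        assert wasserstein_1d([1.0], [4.0], p=2.0) == pytest.approx(3.0)

    def test_normalized_by_reference_range(self):
        a = [0.0, 1.0]
        ref = [0.0, 10.0]
        assert normalized_wasserstein(a, ref) == pytest.approx(
            wasserstein_1d(a, ref) / 10.0)

    def test_constant_reference_guard(self):
        assert normalized_wasserstein([5.0, 5.0], [5.0, 5.0]) == 0.0
        assert normalized_wasserstein([6.0], [5.0, 5.0]) == float("inf")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestAlignedMetrics:
    def test_accuracy_cases(self):
        assert token_accuracy([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert token_accuracy([5, 6], [1, 2]) == 0.0
        assert token_accuracy([1, 2, 3, 9], [1, 2, 3, 4]) == 0.75

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            token_accuracy([1], [1, 2])

    def test_weighted_f1_identity_and_zero(self):
        assert weighted_f1([1, 2, 1], [1, 2, 1]) == 1.0
        assert weighted_f1([2, 2, 2], [1, 1, 1]) == 0.0

    def test_weighted_f1_hand_computed(self):
        # supports (3, 1); class 7 fully correct (F1 1.0), class 8 missed (F1 0)
        pred = [7, 7, 7, 7]
        ref = [7, 7, 7, 8]
        # class 7: P = 3/4, R = 1 -> F1 = 6/7; weighted: (3*(6/7) + 1*0)/4
        assert weighted_f1(pred, ref) == pytest.approx((3 * 6 / 7) / 4)

    def test_weighted_f1_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score

        ref = rng.integers(0, 10, size=500)
        pred = np.where(rng.random(500) < 0.3, rng.integers(0, 10, size=500), ref)
        ours = weighted_f1(pred.tolist(), ref.tolist())
        theirs = f1_score(ref, pred, average="weighted", zero_division=0)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_equals_accuracy_when_classes_all_or_nothing(self):
        # classes 1 and 3 fully correct, class 2's position predicted as a
        # class absent from the reference: weighted F1 collapses to accuracy
        pred = [1, 1, 3, 3, 3, 0]
        ref = [1, 1, 3, 3, 3, 2]
        assert weighted_f1(pred, ref) == pytest.approx(token_accuracy(pred, ref))


class TestBleu4:
    def test_identity_is_100(self):
        seq = [1, 2, 3, 4, 5, 6, 7, 8]
        assert bleu4(seq, seq) == pytest.approx(100.0)

    def test_half_length_brevity_penalty(self):
        ref = list(range(20))
        gen = ref[:10]     # every n-gram of gen appears in ref
        assert bleu4(gen, ref) == pytest.approx(100.0 * np.exp(1 - 2), rel=1e-9)

    def test_disjoint_tokens_zero(self):
        assert bleu4([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == 0.0

    def test_corpus_pooling_differs_from_mean_of_pairs(self):
        gens = [[1, 2, 3, 4], [5, 6, 7, 8, 9, 10, 11, 12]]
        refs = [[1, 2, 3, 4], [5, 6, 7, 8, 13, 14, 15, 16]]
        corpus = bleu4(gens, refs)
        mean_pairs = np.mean([bleu4(g, r) for g, r in zip(gens, refs)])
        assert corpus != pytest.approx(mean_pairs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bleu4([], [1, 2])

    def test_monotone_under_corruption(self, rng):
        ref = rng.integers(0, 50, size=200).tolist()
        scores = []
        for rate in (0.0, 0.1, 0.3, 0.6):
            corrupt = [t if rng.random() > rate else int(rng.integers(50, 100))
                       for t in ref]
            scores.append(bleu4(corrupt, ref))
        assert scores[0] == pytest.approx(100.0)
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestRougeL:
    def test_identity_is_one(self):
        seq = [1, 2, 3, 4, 5]
        assert rouge_l(seq, seq) == pytest.approx(1.0)
        assert rouge_l(seq, seq, standard=True) == pytest.approx(1.0)

    def test_disjoint_zero(self):
        assert rouge_l([1, 2, 3], [4, 5, 6]) == 0.0

    def test_printed_form_reduces_to_lcs_over_reference_length(self):
        gen, ref = [1, 2, 9, 9], [1, 2, 3, 4, 5]
        assert rouge_l(gen, ref) == pytest.approx(lcs_length(gen, ref) / len(ref))

    def test_standard_form_is_lcs_f_measure(self):
        gen, ref = [1, 2, 9, 9], [1, 2, 3, 4, 5]
        lcs = lcs_length(gen, ref)
        r, p = lcs / len(ref), lcs / len(gen)
        beta = r / p
        expected = (1 + beta ** 2) * r * p / (r + beta ** 2 * p)
        assert rouge_l(gen, ref, standard=True) == pytest.approx(expected)

    def test_average_over_pairs(self):
        gens = [[1, 2, 3], [4, 5]]
        refs = [[1, 2, 3], [6, 7]]
        assert rouge_l(gens, refs) == pytest.approx(0.5)

    def test_monotone_under_corruption(self, rng):
        ref = rng.integers(0, 50, size=150).tolist()
        scores = []
        for rate in (0.0, 0.2, 0.5, 0.9):
            corrupt = [t if rng.random() > rate else int(rng.integers(50, 100))
                       for t in ref]
            scores.append(rouge_l(corrupt, ref))
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m["r2"], m["rmse"], m["mape"]) == (1.0, 0.0, 0.0)

    def test_constant_predictor_r2_zero(self):
        true = [1.0, 2.0, 3.0, 4.0]
        m = regression_metrics([2.5] * 4, true)
        assert m["r2"] == pytest.approx(0.0)

    def test_hand_computed_five_points(self):
        true = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        pred = np.array([1.5, 1.5, 4.0, 6.0, 7.0])
        resid = true - pred
        m = regression_metrics(pred, true)
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean(resid ** 2)))
        assert m["r2"] == pytest.approx(1 - resid @ resid / np.sum((true - 4.0) ** 2))
        assert m["mape"] == pytest.approx(np.mean(np.abs(resid / true)) * 100)

    def test_zero_true_excluded_from_mape(self):
        m = regression_metrics([1.0, 1.0], [0.0, 2.0])
        assert m["mape_excluded"] == 1
        assert m["mape"] == pytest.approx(50.0)


class TestEvaluateSequences:
    def test_aligned_report_pools_positions(self):
        preds = [[1, 2, 3], [4, 5, 6]]
        refs = [[1, 2, 9], [4, 5, 6]]
        rep = evaluate_sequences(preds, refs, aligned=True)
        assert rep.accuracy == pytest.approx(5 / 6)
        assert rep.bleu4_percent <= 100.0
        assert 0 <= rep.rouge_l <= 1

    def test_unaligned_report_has_no_accuracy(self):
        rep = evaluate_sequences([[1, 2, 3, 4]], [[1, 2, 3, 4, 5]])
        assert rep.accuracy is None and rep.weighted_f1 is None
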