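"""Metric oracles: every hand-enumerable example is checked against an
independent computation (sklearn confusion math, explicit matrix powers,
traced greedy matching) rather than against the implementation itself."""

import numpy as np
import pytest
from sklearn.metrics import f1_score

from schicenh.metrics import (
    LoopSet,
    binarized_macro_f1,
    compare_matrices,
    flexible_match_prf,
    mae,
    match_loops,
    random_walk_concordance,
    stratum_adjusted_correlation,
)


def random_symmetric(rng, n, lam=4.0):
    upper = np.triu(rng.poisson(lam, size=(n, n)).astype(float))
    return upper + np.triu(upper, k=1).T


class TestMae:
    def test_identical_is_zero(self, rng):
        a = random_symmetric(rng, 6)
        assert mae(a, a) == 0.0

    def test_hand_case(self):
        assert mae([[0, 1], [1, 0]], [[1, 1], [1, 1]]) == 0.5

    def test_symmetric_in_arguments(self, rng):
        a, b = random_symmetric(rng, 5), random_symmetric(rng, 5)
        assert mae(a, b) == mae(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBinarizedMacroF1:
    def test_self_comparison_is_one(self, rng):
        t = random_symmetric(rng, 8, lam=0.5)
        t[0, 1] = t[1, 0] = 3  # ensure a nonzero
        assert binarized_macro_f1(t, t) == 1.0

    def test_total_disagreement_is_zero(self):
        truth = np.array([[0, 1], [1, 3]], dtype=float)
        pred = np.array([[2, 0], [0, 0]], dtype=float)
        assert binarized_macro_f1(pred, truth) == 0.0

    def test_oversmoothed_prediction_vs_sklearn_oracle(self):
        truth = np.array(
            [[0, 2, 0, 0], [2, 0, 0, 3], [0, 0, 0, 0], [0, 3, 0, 5]], dtype=float
        )
        tau = 2.0  # smallest nonzero in truth
        pred = truth + np.where(truth == 0, tau, 0.0)  # fully densified
        got = binarized_macro_f1(pred, truth)
        oracle = f1_score((truth >= tau).ravel(), (pred >= tau).ravel(),
                          average="macro", zero_division=0.0)
        assert got == pytest.approx(oracle)
        assert got < 1.0

    def test_random_cases_match_sklearn(self, rng):
        for _ in range(10):
            truth = random_symmetric(rng, 6, lam=0.8)
            if not truth.any():
                continue
            pred = random_symmetric(rng, 6, lam=0.8)
            tau = truth[truth > 0].min()
            t, p = (truth >= tau).ravel(), (pred >= tau).ravel()
            if t.all() or p.all() or not t.any() or not p.any():
                continue  # sklearn's zero_division convention differs on empty classes
            assert binarized_macro_f1(pred, truth) == pytest.approx(
                f1_score(t, p, average="macro"))

    def test_all_zero_truth_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            binarized_macro_f1(np.ones((2, 2)), np.zeros((2, 2)))


class TestSCC:
    def test_self_correlation_is_one(self, rng):
        a = random_symmetric(rng, 10)
        assert stratum_adjusted_correlation(a, a) == pytest.approx(1.0)

    def test_affine_transform_is_one(self, rng):
        a = random_symmetric(rng, 10)
        assert stratum_adjusted_correlation(a, 2 * a + 5) == pytest.approx(1.0)

    def test_negated_centered_is_minus_one(self, rng):
        # with no smoothing, each stratum of b is an affine flip of a
        a = random_symmetric(rng, 10)
        b = np.zeros_like(a)
        for d in range(10):
            idx = np.arange(10 - d)
            vals = a[idx, idx + d]
            b[idx, idx + d] = -(vals - vals.mean())
            b[idx + d, idx] = b[idx, idx + d]
        assert stratum_adjusted_correlation(a, b, smoothing_span=0) == pytest.approx(-1.0)

    def test_degenerate_strata_rejected(self):
        with pytest.raises(ValueError, match="strata"):
            stratum_adjusted_correlation(np.ones((4, 4)), np.ones((4, 4)))

    def test_weighted_average_against_direct_computation(self, rng):
        from scipy.stats import rankdata

        a, b = random_symmetric(rng, 12), random_symmetric(rng, 12)
        h, D = 1, 6
        got = stratum_adjusted_correlation(a, b, smoothing_span=h, max_distance_bins=D)
        # independent recomputation with explicit loops
        from scipy.ndimage import uniform_filter

        def smooth(x):
            size = 2 * h + 1
            num = uniform_filter(x, size=size, mode="constant")
            den = uniform_filter(np.ones_like(x), size=size, mode="constant")
            return num / den

        sa, sb = smooth(a), smooth(b)
        num = den = 0.0
        for d in range(D + 1):
            xs, ys = np.diagonal(sa, d), np.diagonal(sb, d)
            if xs.std() == 0 or ys.std() == 0:
                continue
            w = len(xs) * np.std(rankdata(xs)) * np.std(rankdata(ys))
            num += w * np.corrcoef(xs, ys)[0, 1]
            den += w
        assert got == pytest.approx(num / den)


class TestConcordance:
    def test_identical_is_one(self, rng):
        a = random_symmetric(rng, 8)
        assert random_walk_concordance(a, a) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        a, b = random_symmetric(rng, 8), random_symmetric(rng, 8)
        assert random_walk_concordance(a, b) == pytest.approx(random_walk_concordance(b, a))

    def test_hand_pair_matches_matrix_arithmetic(self):
        a = np.array([[0, 2, 0, 0, 1, 0], [2, 0, 1, 0, 0, 0], [0, 1, 0, 3, 0, 0],
                      [0, 0, 3, 0, 1, 0], [1, 0, 0, 1, 0, 2], [0, 0, 0, 0, 2, 0]], float)
        b = np.array([[0, 1, 0, 0, 1, 0], [1, 0, 2, 0, 0, 0], [0, 2, 0, 1, 0, 0],
                      [0, 0, 1, 0, 2, 0], [1, 0, 0, 2, 0, 1], [0, 0, 0, 0, 1, 0]], float)
        ta = a / a.sum(axis=1, keepdims=True)
        tb = b / b.sum(axis=1, keepdims=True)
        expected = 1.0 - np.abs(ta - tb).sum() / ((6 + 6) / 2)
        assert random_walk_concordance(a, b, steps=1) == pytest.approx(expected)

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            random_walk_concordance(np.zeros((3, 3)), np.zeros((3, 3)))


class TestFlexibleMatch:
    def test_exact_agreement(self):
        p, r, f = flexible_match_prf({3, 9}, {3, 9}, shift=0, n_bins=20)
        assert p == r == 1.0 and f == 1.0

    def test_shift_window_rule(self):
        p0, r0, _ = flexible_match_prf({5}, {7}, shift=1, n_bins=20)
        assert p0 == 0.0 and r0 == 0.0
        p1, r1, _ = flexible_match_prf({5}, {7}, shift=2, n_bins=20)
        assert p1 == 1.0 and r1 == 1.0

    def test_one_to_one_constraint(self):
        for s in (0, 1, 3):
            p, r, _ = flexible_match_prf({3, 4}, {4}, shift=s, n_bins=20)
            assert r == 1.0
            assert p == 0.5  # exactly one TP, one FP

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError):
            flexible_match_prf({1}, {1}, shift=-1, n_bins=5)


class TestMatchLoops:
    def test_identical_sets(self):
        loops = LoopSet([(3, 9), (10, 20)])
        p, r, f, n_exact = match_loops(loops, loops)
        assert p == r == 1.0 and n_exact == 2

    def test_single_pixel_shift_matches(self):
        p, r, _, n_exact = match_loops(LoopSet([(10, 20)]), LoopSet([(11, 21)]), pixel_shift=1)
        assert p == r == 1.0 and n_exact == 0

    def test_two_pixel_shift_does_not_match(self):
        p, r, _, _ = match_loops(LoopSet([(10, 20)]), LoopSet([(12, 22)]), pixel_shift=1)
        assert p == 0.0 and r == 0.0

    def test_invalid_anchor_order_rejected(self):
        with pytest.raises(ValueError):
            LoopSet([(5, 5)])


class TestInvariantsAndProperties:
    def test_all_metrics_perfect_on_self(self, rng):
        a = random_symmetric(rng, 12)
        rep = compare_matrices(a, a)
        assert rep.mae == 0.0
        assert rep.macro_f1 == 1.0
        assert rep.scc == pytest.approx(1.0)
        assert rep.disco == pytest.approx(1.0)

    def test_noise_monotonically_degrades_scc_and_disco(self, rng):
        a = random_symmetric(rng, 30, lam=6.0)
        amp_scores = []
        for amp in (0.1, 1.0, 5.0):
            sccs, discos = [], []
            for seed in range(20):
                noise_rng = np.random.default_rng(seed)
                noise = np.abs(noise_rng.normal(0, amp, size=a.shape))
                noise = np.triu(noise) + np.triu(noise, 1).T
                b = a + noise
                sccs.append(stratum_adjusted_correlation(a, b))
                discos.append(random_walk_concordance(a, b))
            amp_scores.append((np.mean(sccs), np.mean(discos)))
        sccs, discos = zip(*amp_scores)
        assert sccs[0] > sccs[1] > sccs[2]
        assert discos[0] > discos[1] > discos[2]

    def test_oversmoothing_detector(self, rng):
        # sparse truth: predicting the exact support beats predicting everywhere
        truth = random_symmetric(rng, 12, lam=0.3)
        truth[0, 1] = truth[1, 0] = 2
        tau = truth[truth > 0].min()
        support_pred = truth.copy()
        dense_pred = truth + np.where(truth == 0, tau, 0.0)
        assert binarized_macro_f1(dense_pred, truth) < binarized_macro_f1(support_pred, truth)
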