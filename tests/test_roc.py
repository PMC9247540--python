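import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fluidresp.roc import (
    DegenerateLabelsError,
    VarianceUndefinedError,
    delong_ci,
    delong_paired_test,
    empirical_roc,
    youden_best_cutoff,
)


def auc_pair_counting(pos, neg):
    """Brute-force O(n^2) Mann-Whitney oracle (ties count half)."""
    total = 0.0
    for p in pos:
        for q in neg:
            total += (p > q) + 0.5 * (p == q)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Naive scan of J over every midpoint-plus-sentinel cutoff."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    u = np.unique(scores)
    cands = [-math.inf] + [(a + b) / 2 for a, b in zip(u, u[1:])] + [math.inf]
    best = None
    for c in cands:
        sn = np.mean(scores[labels] >= c)
        sp = np.mean(scores[~labels] < c)
        j = sn + sp - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sn, sp)
    return best


class TestEmpiricalAuc:
    def test_small_example(self):
        r = empirical_roc([3, 5, 7, 1, 2, 6],
                          [True, True, True, False, False, False])
        assert r.auc == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        r = empirical_roc([10, 11, 1, 2], [True, True, False, False])
        assert r.auc == 1.0
        assert r.auc_ci == (1.0, 1.0)  # zero DeLong variance

    def test_all_tied_scores(self):
        r = empirical_roc([5.0] * 6, [True] * 3 + [False] * 3)
        assert r.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            empirical_roc([1, 2, 3], [True, True, True])

    @pytest.mark.parametrize("n,seed", [(10, 0), (50, 1), (200, 2)])
    def test_matches_pair_counting_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = empirical_roc(scores, labels)
        assert r.auc == pytest.approx(
            auc_pair_counting(scores[labels], scores[~labels]), abs=1e-12)

    @given(st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.arange(20) < 8
        a = empirical_roc(scores, labels).auc
        b = empirical_roc(np.exp(scores), labels).auc
        c = empirical_roc(3 * scores - 7, labels).auc
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(3)
        r = empirical_roc(rng.normal(size=40), rng.random(40) < 0.5)
        assert r.sens[0] == 1.0 and r.spec[0] == 0.0
        assert r.sens[-1] == 0.0 and r.spec[-1] == 1.0
        assert np.all(np.diff(r.sens) <= 0)
        assert np.all(np.diff(r.spec) >= 0)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]


class TestDelongCi:
    # fixed binormal sample; interval frozen from an independent
    # R pROC (DeLong) run on the same numbers
    POS = [1.305, -0.04, 1.75, 1.941, -0.951, -0.302, 1.128, 0.684,
           0.983, 0.147, 1.879, 1.778, 1.066, 2.127]
    NEG = [0.468, -0.859, 0.369, -0.959, 0.878, -0.05, -0.185, -0.681,
           1.223, -0.155, -0.428, -0.352, 0.532, 0.365, 0.413, 0.431,
           2.142, -0.406]

    def _data(self):
        scores = np.array(self.POS + self.NEG)
        labels = np.array([True] * len(self.POS) + [False] * len(self.NEG))
        return scores, labels

    def test_matches_reference_implementation(self):
        scores, labels = self._data()
        r = empirical_roc(scores, labels)
        assert r.auc == pytest.approx(0.753968253968254, abs=1e-12)
        assert r.auc_ci[0] == pytest.approx(0.568369706756, abs=1e-9)
        assert r.auc_ci[1] == pytest.approx(0.939566801181, abs=1e-9)

    def test_direction_swap_mirrors_interval(self):
        scores, labels = self._data()
        lo, hi = delong_ci(scores, labels)
        lo2, hi2 = delong_ci(scores, ~labels)
        assert lo2 == pytest.approx(1 - hi, abs=1e-12)
        assert hi2 == pytest.approx(1 - lo, abs=1e-12)

    def test_variance_undefined_for_single_positive(self):
        with pytest.raises(VarianceUndefinedError):
            delong_ci([1, 2, 3, 4], [True, False, False, False])

    def test_coverage_of_true_auc(self):
        # binormal markers with true AUC 0.8 at the study's sample size
        true_auc = 0.8
        mu = math.sqrt(2) * stats.norm.ppf(true_auc)
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            pos = rng.normal(mu, 1, 13)
            neg = rng.normal(0, 1, 19)
            lo, hi = delong_ci(np.r_[pos, neg],
                               np.r_[np.ones(13), np.zeros(19)].astype(bool))
            hits += lo <= true_auc <= hi
        assert 0.90 <= hits / n_sim <= 0.99


class TestPairedDelong:
    def test_marker_vs_itself(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=30)
        y = np.arange(30) < 12
        a, b, z, p = delong_paired_test(s, s, y)
        assert a == b and z == 0.0 and p == 1.0

    def test_monotone_transform_is_equivalent(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        y = np.arange(30) < 12
        a, b, z, p = delong_paired_test(s, np.exp(s), y)
        assert a == pytest.approx(b)
        assert p == 1.0

    def test_power_against_uninformative_marker(self):
        # informative (AUC 0.8) vs pure-noise marker at n = 500
        mu = math.sqrt(2) * stats.norm.ppf(0.8)
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            y = np.r_[np.ones(250), np.zeros(250)].astype(bool)
            a = np.where(y, rng.normal(mu, 1, 500), rng.normal(0, 1, 500))
            b = rng.normal(size=500)
            *_, p = delong_paired_test(a, b, y)
            rejections += p < 0.05
        assert rejections / n_sim > 0.95

    def test_too_few_pairs_rejected(self):
        with pytest.raises(VarianceUndefinedError):
            delong_paired_test([1, 2, 3], [1, 2, 3], [True, False, False])


class TestYoudenCutoff:
    def test_separated_groups(self):
        res = youden_best_cutoff([1, 2, 3, 4], [False, False, True, True])
        assert res.youden_j == 1.0
        assert 2 < res.cutoff <= 3
        assert res.sens == 1.0 and res.spec == 1.0

    def test_all_tied(self):
        res = youden_best_cutoff([5.0] * 6, [True] * 3 + [False] * 3)
        assert res.youden_j == 0.0

    def test_j_consistency(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=50)
        y = rng.random(50) < 0.4
        res = youden_best_cutoff(s, y)
        assert res.youden_j == pytest.approx(res.sens + res.spec - 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 60))
        s = np.round(rng.normal(size=n), 1)
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        res = youden_best_cutoff(s, y)
        j, c, sn, sp = youden_exhaustive(s, y)
        assert res.youden_j == pytest.approx(j)
        assert res.cutoff == pytest.approx(c)

    def test_lower_is_positive_direction(self):
        res = youden_best_cutoff([1, 2, 3, 4], [True, True, False, False],
                                 direction="lower_is_positive")
        assert res.youden_j == 1.0
        assert 2 <= res.cutoff < 3
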