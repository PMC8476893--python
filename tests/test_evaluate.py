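"""Confusion metrics, exact Clopper–Pearson intervals, AUC, per-gene DE."""

import numpy as np
import pytest
from scipy import stats

from gpsig import (
    DataError,
    ExpressionMatrix,
    clopper_pearson_ci,
    confusion_metrics,
    confusion_metrics_from_counts,
    roc_auc,
    signature_gene_de,
)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,sens,spec,acc",
        [
            (58, 12, 36, 5, 82.86, 87.80, 84.68),   # training cohort counts
            (17, 2, 14, 9, 89.47, 60.87, 73.81),    # first public validation
            (10, 2, 13, 8, 83.33, 61.90, 69.70),    # in-house cohort
            (23, 1, 20, 2, 95.83, 90.91, 93.48),    # second public validation
        ],
    )
    def test_reported_cohort_counts(self, tp, fn, tn, fp, sens, spec, acc):
        rep = confusion_metrics_from_counts(tp, fn, tn, fp)
        assert round(rep.sensitivity * 100, 2) == sens
        assert round(rep.specificity * 100, 2) == spec
        assert round(rep.accuracy * 100, 2) == acc
        assert rep.accuracy_ci_95[0] <= rep.accuracy <= rep.accuracy_ci_95[1]

    def test_all_correct(self):
        rep = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        yhat = rng.integers(0, 2, 40)
        y = rng.integers(0, 2, 40)
        base = confusion_metrics(yhat, y)
        perm = rng.permutation(40)
        assert confusion_metrics(yhat[perm], y[perm]) == base

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            confusion_metrics([], [])


def cp_interval_by_test_inversion(k: int, n: int, alpha: float = 0.05,
                                  tol: float = 1e-9) -> tuple[float, float]:
    """Independent oracle: invert the exact binomial test by bisection.

    Lower limit: smallest p with P(X >= k | p) > alpha/2.
    Upper limit: largest p with P(X <= k | p) > alpha/2.
    """
    def upper_tail(p):  # P(X >= k)
        return stats.binom.pmf(np.arange(k, n + 1), n, p).sum()

    def lower_tail(p):  # P(X <= k)
        return stats.binom.pmf(np.arange(0, k + 1), n, p).sum()

    if k == 0:
        low = 0.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if upper_tail(mid) > alpha / 2:
                hi = mid
            else:
                lo = mid
        low = (lo + hi) / 2
    if k == n:
        high = 1.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if lower_tail(mid) > alpha / 2:
                lo = mid
            else:
                hi = mid
        high = (lo + hi) / 2
    return low, high


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson_ci(0, 10)[0] == 0.0
        assert clopper_pearson_ci(10, 10)[1] == 1.0

    def test_all_successes_closed_form(self):
        # low = (alpha/2)^(1/n) = 0.025^(1/10)
        low, high = clopper_pearson_ci(10, 10)
        assert low == pytest.approx(0.025 ** 0.1, abs=1e-12)
        assert low == pytest.approx(0.6915, abs=5e-5)

    def test_accuracy_interval_matches_inversion_oracle(self):
        low, high = clopper_pearson_ci(94, 111)
        olow, ohigh = cp_interval_by_test_inversion(94, 111)
        assert low == pytest.approx(olow, abs=1e-6)
        assert high == pytest.approx(ohigh, abs=1e-6)

    @pytest.mark.parametrize("n", [1, 2, 5, 11, 18, 24, 30])
    def test_matches_inversion_oracle_for_all_k(self, n):
        for k in range(n + 1):
            low, high = clopper_pearson_ci(k, n)
            olow, ohigh = cp_interval_by_test_inversion(k, n)
            assert low == pytest.approx(olow, abs=1e-6), (k, n)
            assert high == pytest.approx(ohigh, abs=1e-6), (k, n)

    def test_invalid_counts(self):
        with pytest.raises(DataError):
            clopper_pearson_ci(5, 0)
        with pytest.raises(DataError):
            clopper_pearson_ci(7, 5)


def auc_by_pair_counting(scores, truth) -> float:
    """Independent oracle: concordant-pair fraction with ties counted 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, ci = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_small_case_matches_exhaustive_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.7, 0.2, 0.55]
        truth = [0, 1, 0, 1, 1, 1, 0, 0]
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(auc_by_pair_counting(scores, truth), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_cases_up_to_20_samples_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        truth = np.zeros(n, dtype=int)
        truth[: max(1, n // 3)] = 1
        rng.shuffle(truth)
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        auc, ci = roc_auc(scores, truth)
        assert auc == pytest.approx(auc_by_pair_counting(scores, truth), abs=1e-12)
        assert 0.0 <= ci[0] <= auc <= ci[1] <= 1.0

    def test_null_scores_give_auc_near_half(self):
        rng = np.random.default_rng(99)
        truth = np.array([1] * 200 + [0] * 200)
        auc, _ = roc_auc(rng.random(400), truth)
        assert abs(auc - 0.5) <= 0.08

    def test_one_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.9], [1, 1])


class TestSignatureGeneDE:
    def _expr(self, values, genes=None):
        genes = genes or tuple(f"g{i}" for i in range(values.shape[0]))
        return ExpressionMatrix(genes, tuple(f"s{i}" for i in range(values.shape[1])),
                                values)

    def test_zero_variance_gene_is_na(self):
        values = np.vstack([np.ones(10), np.random.default_rng(0).normal(size=10)])
        expr = self._expr(values)
        table, n_de = signature_gene_de(expr, [1] * 5 + [0] * 5, ["g0"])
        assert np.isnan(table.loc["g0", "p"])
        assert n_de == 0

    def test_planted_mean_shift_detected(self):
        rng = np.random.default_rng(1)
        truth = np.array([1] * 30 + [0] * 30)
        shifted = rng.normal(0, 1, 60) + 2.0 * truth  # delta = 2 SD
        values = np.vstack([shifted, rng.normal(0, 1, 60)])
        table, n_de = signature_gene_de(self._expr(values), truth, ["g0", "g1"])
        assert table.loc["g0", "p"] < 0.05
        assert n_de >= 1

    def test_null_genes_reject_at_about_alpha(self):
        rng = np.random.default_rng(2)
        truth = np.array([1] * 25 + [0] * 25)
        values = rng.normal(8, 1, size=(1000, 50))
        expr = self._expr(values)
        _, n_de = signature_gene_de(expr, truth, list(expr.gene_ids))
        assert 0.02 <= n_de / 1000 <= 0.09

    def test_missing_gene_rejected(self):
        expr = self._expr(np.zeros((1, 4)))
        with pytest.raises(DataError, match="zz"):
            signature_gene_de(expr, [1, 1, 0, 0], ["zz"])
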