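"""Validation statistics against brute-force oracles and worked examples."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepachrom.assays import get_assay
from hepachrom.dataset import get_scheme
from hepachrom.metrics import (
    PairedMeasurements,
    ReplicateSeries,
    category_scores,
    class_counts,
    class_metrics,
    clia_check,
    confusion_matrix,
    corrected_after_dilution,
    cv_percent,
    dilution_advice,
    limit_of_detection,
    macro_class_metrics,
    macro_ovr_auc,
    pearson_r,
    percent_variation,
    regression_metrics,
    roc_auc,
)

TB_SCHEME = get_scheme("total-bilirubin")

finite_floats = st.floats(min_value=-100, max_value=100, allow_nan=False)


# ---------------------------------------------------------------- oracles --
def pearson_oracle(x, y):
    """Direct summation of the centred product-moment formula."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(
        sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y)
    )
    return num / den


def regression_oracle(true, pred):
    n = len(true)
    errs = [p - t for t, p in zip(true, pred)]
    mae = sum(abs(e) for e in errs) / n
    rmse = math.sqrt(sum(e * e for e in errs) / n)
    mt = sum(true) / n
    sse = sum(e * e for e in errs)
    sst = sum((t - mt) ** 2 for t in true)
    return mae, rmse, 1 - sse / sst


def auc_pair_counting_oracle(scores, labels):
    """Mann-Whitney: fraction of (positive, negative) pairs ranked
    correctly, ties counting half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def cv_oracle(values):
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return 100.0 * sd / mean


# ---------------------------------------------------------------- pearson --
class TestPearsonR:
    def test_perfect_correlation(self):
        assert pearson_r(PairedMeasurements((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))) == pytest.approx(1.0)

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(PairedMeasurements((1.0, 1.0), (1.0, 2.0)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(finite_floats, finite_floats), min_size=3, max_size=20))
    def test_matches_direct_summation_oracle(self, pairs):
        x = tuple(p[0] for p in pairs)
        y = tuple(p[1] for p in pairs)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        got = pearson_r(PairedMeasurements(x, y))
        assert got == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_invariant_under_positive_affine_rescaling(self, a, b):
        x = (0.52, 2.13, 8.25, 12.45, 17.1)
        y = (0.55, 2.20, 8.89, 12.90, 17.60)
        base = pearson_r(PairedMeasurements(x, y))
        scaled = pearson_r(PairedMeasurements(tuple(a * xi + b for xi in x), y))
        assert scaled == pytest.approx(base, abs=1e-12)


# ------------------------------------------------- % variation and CLIA --
class TestPercentVariation:
    @pytest.mark.parametrize("x,y,expected", [(0.52, 0.55, 5.77), (2.13, 2.20, 3.29)])
    def test_worked_examples(self, x, y, expected):
        assert round(percent_variation(x, y), 2) == expected

    def test_identical_readings_give_zero(self):
        assert percent_variation(4.2, 4.2) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_variation(0.0, 1.0)


class TestCliaCheck:
    def test_small_deviation_passes(self):
        assert clia_check(0.52, 0.55)

    def test_large_deviation_fails(self):
        assert not clia_check(10.0, 11.5)

    def test_boundary_is_inclusive(self):
        assert clia_check(10.0, 11.0)


# ------------------------------------------------------------ regression --
class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.mae, m.rmse, m.r2) == (0.0, 0.0, 1.0)

    def test_hand_arithmetic_example(self):
        m = regression_metrics([0.0, 10.0], [1.0, 9.0])
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1 - 2 / 50)

    def test_constant_true_sequence_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([2.0, 2.0], [1.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(finite_floats, finite_floats), min_size=2, max_size=20))
    def test_matches_loop_oracle(self, pairs):
        true = [p[0] for p in pairs]
        pred = [p[1] for p in pairs]
        if np.ptp(true) == 0:
            return
        m = regression_metrics(true, pred)
        mae, rmse, r2 = regression_oracle(true, pred)
        assert m.mae == pytest.approx(mae, abs=1e-12)
        assert m.rmse == pytest.approx(rmse, abs=1e-12)
        assert m.r2 == pytest.approx(r2, abs=1e-9)


# ------------------------------------------------------- classification --
def _random_labels(rng, n):
    return list(rng.choice(TB_SCHEME.names, size=n))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = list(TB_SCHEME.names) * 3
        mat = confusion_matrix(labels, labels, TB_SCHEME)
        assert (mat.values.sum() == 15) and np.all(np.diag(mat.values) == 3)
        assert mat.values.sum() - np.trace(mat.values) == 0

    def test_entries_sum_to_sample_count(self):
        rng = np.random.default_rng(0)
        t, p = _random_labels(rng, 180), _random_labels(rng, 180)
        assert confusion_matrix(t, p, TB_SCHEME).values.sum() == 180

    def test_single_sample_has_one_nonzero_cell(self):
        mat = confusion_matrix(["Low"], ["High"], TB_SCHEME)
        assert mat.values.sum() == 1 and mat.loc["Low", "High"] == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["Lowish"], ["Low"], TB_SCHEME)

    def test_marginals_conserved_under_permutation(self):
        rng = np.random.default_rng(1)
        t, p = _random_labels(rng, 60), _random_labels(rng, 60)
        mat1 = confusion_matrix(t, p, TB_SCHEME)
        perm = rng.permutation(60)
        mat2 = confusion_matrix([t[i] for i in perm], [p[i] for i in perm], TB_SCHEME)
        assert mat1.equals(mat2)


class TestClassMetrics:
    def test_direct_substitution(self):
        # TP=9, TN=9, FP=1, FN=1 -> all three ratios 0.9
        t = ["Low"] * 10 + ["High"] * 10
        p = ["Low"] * 9 + ["High"] + ["High"] * 9 + ["Low"]
        mat = confusion_matrix(t, p, TB_SCHEME)
        m = class_metrics(mat, "Low")
        assert (m.accuracy, m.sensitivity, m.specificity) == (0.9, 0.9, 0.9)

    def test_perfect_diagonal_gives_ones_everywhere(self):
        labels = list(TB_SCHEME.names) * 2
        mat = confusion_matrix(labels, labels, TB_SCHEME)
        macro = macro_class_metrics(mat)
        assert (macro.accuracy, macro.sensitivity, macro.specificity) == (1.0, 1.0, 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        t, p = _random_labels(rng, 40), _random_labels(rng, 40)
        mat = confusion_matrix(t, p, TB_SCHEME)
        for cls in TB_SCHEME.names:
            c = class_counts(mat, cls)
            tp = sum(1 for a, b in zip(t, p) if a == cls and b == cls)
            fn = sum(1 for a, b in zip(t, p) if a == cls and b != cls)
            fp = sum(1 for a, b in zip(t, p) if a != cls and b == cls)
            tn = sum(1 for a, b in zip(t, p) if a != cls and b != cls)
            assert (c.tp, c.fn, c.fp, c.tn) == (tp, fn, fp, tn)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_uninformative_scores_give_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [True, False, True, False]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.integers(min_value=0, max_value=5), min_size=6, max_size=6),
        labels=st.lists(st.booleans(), min_size=6, max_size=6),
    )
    def test_matches_pair_counting_oracle(self, scores, labels):
        if all(labels) or not any(labels):
            return
        got = roc_auc([float(s) for s in scores], labels)
        assert got == pytest.approx(auc_pair_counting_oracle(scores, labels), abs=1e-12)

    def test_macro_ovr_scores_peak_at_own_bin(self):
        scores = category_scores([2.0], TB_SCHEME)
        assert scores.shape == (1, 5)
        assert scores.argmax() == 1  # 2.0 mg/dL sits in the "Low" bin

    def test_macro_ovr_auc_perfect_when_predictions_equal_truth(self):
        concs = [0.2, 1.0, 5.0, 10.0, 15.0]
        labels = ["Very Low", "Low", "Normal", "High", "Very High"]
        assert macro_ovr_auc(concs, labels, TB_SCHEME) == 1.0


# ------------------------------------------------------------- precision --
class TestCvPercent:
    def test_constant_series_has_zero_cv(self):
        assert cv_percent(ReplicateSeries((10.0, 10.0, 10.0))) == 0.0

    def test_forced_arithmetic(self):
        assert cv_percent(ReplicateSeries((9.0, 10.0, 11.0))) == pytest.approx(10.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(ReplicateSeries((-1.0, 1.0)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1, max_value=100), min_size=2, max_size=20))
    def test_matches_two_pass_oracle(self, values):
        got = cv_percent(ReplicateSeries(tuple(values)))
        assert got == pytest.approx(cv_oracle(values), abs=1e-9)


# -------------------------------------------------------------- LOD ------
class TestLimitOfDetection:
    def test_zero_variance_blanks_give_zero_lod(self):
        assert limit_of_detection([0.5, 0.5, 0.5, 0.5, 0.5], 0.3) == 0.0

    def test_three_sd_over_slope(self):
        blanks = [0.0, 0.01, 0.02, 0.01, 0.0]  # sample SD computed directly
        sd = np.std(blanks, ddof=1)
        assert limit_of_detection(blanks, 0.3) == pytest.approx(3 * sd / 0.3)

    def test_scales_linearly_with_blank_sd(self):
        blanks = np.array([0.0, 0.01, 0.02, 0.015, 0.005])
        lod1 = limit_of_detection(blanks, 0.3)
        lod2 = limit_of_detection(2 * blanks, 0.3)
        assert lod2 == pytest.approx(2 * lod1)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            limit_of_detection([0.0, 0.01], 0.0)


# -------------------------------------------------------------- dilution --
class TestDilutionAdvice:
    def test_over_range_sample_triggers_one_to_five_advice(self):
        a = get_assay("direct-bilirubin")
        advice = dilution_advice(25.0, a)
        assert advice.needs_dilution and advice.factor == 5

    def test_in_range_sample_needs_no_dilution(self):
        a = get_assay("direct-bilirubin")
        assert not dilution_advice(12.0, a).needs_dilution

    def test_corrected_value_multiplies_by_factor(self):
        assert corrected_after_dilution(4.6, 5) == pytest.approx(23.0)
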