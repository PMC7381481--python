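"""Tests for the first-principles diagnostic statistics.

Wherever an established library implements the same statistic, it serves as
an independent cross-check of the formulaic implementation (scipy for
correlations and Fisher's test, pingouin for the ICC).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from imrangio.diagnostics import (
    bland_altman,
    chi2_2x2,
    classify_responders,
    confusion_at_cutoff,
    correlations,
    fisher_exact_2x2,
    icc_absolute_agreement,
    roc_and_youden,
)
from imrangio.exceptions import (
    DegenerateLabelsError,
    ImrAngioError,
    IncompleteDesignError,
    PairingError,
    UndefinedCorrelationError,
)
from imrangio.indices import IndexPanel


def brute_force_auc(scores, labels):
    """Mann-Whitney pair count: P(pos > neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_and_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.youden_cutoff == 2.5
        assert roc.youden_j == 1.0

    def test_identical_scores_uninformative(self):
        roc = roc_and_youden([5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_and_youden([1, 2, 3], [1, 1, 1])

    @given(st.data())
    @settings(deadline=None, max_examples=150)
    def test_auc_equals_pair_count(self, data):
        n = data.draw(st.integers(2, 50))
        scores = data.draw(
            st.lists(
                st.integers(-5, 5).map(float), min_size=n, max_size=n
            )
        )
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(labels) in (0, n):
            labels[0] = 1 - labels[0]
        roc = roc_and_youden(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_roc_monotonicity(self, data):
        n = data.draw(st.integers(4, 40))
        scores = data.draw(st.lists(st.floats(-10, 10), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(labels) in (0, n):
            labels[0] = 1 - labels[0]
        roc = roc_and_youden(scores, labels)
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)
        assert np.all(np.diff(roc.specificity) >= -1e-12)

    def test_youden_j_is_maximum(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = (scores + rng.normal(scale=0.5, size=30)) > 0
        roc = roc_and_youden(scores, labels)
        j = roc.sensitivity + roc.specificity - 1
        assert roc.youden_j == pytest.approx(j.max())


class TestConfusion:
    def test_seven_discordant_of_92(self):
        # 85 concordant, 7 discordant classifications at the 40U threshold
        scores = [50.0] * 40 + [30.0] * 45 + [50.0] * 4 + [30.0] * 3
        labels = [1] * 40 + [0] * 45 + [0] * 4 + [1] * 3
        conf = confusion_at_cutoff(scores, labels, 40.0)
        assert conf.n == 92
        assert conf.fp + conf.fn == 7
        assert conf.accuracy == pytest.approx(85 / 92)
        assert round(100 * conf.accuracy, 1) == 92.4

    def test_perfect_table(self):
        conf = confusion_at_cutoff([41, 42, 43, 1, 2, 3], [1, 1, 1, 0, 0, 0], 40.0)
        assert (conf.tp, conf.fp, conf.fn, conf.tn) == (3, 0, 0, 3)
        assert conf.sensitivity == conf.specificity == conf.accuracy == 1.0

    def test_nearest_consistent_table_to_reported_metrics(self):
        """tp=30, fp=1, fn=6, tn=55 reproduces the reported sensitivity 83%
        and PPV 96.8% (the full printed quintet is internally inconsistent —
        a 100% specificity forces a 100% PPV — so no single table matches all
        five; this is the nearest-consistent table for n=92)."""
        scores = [41.0] * 30 + [41.0] * 1 + [39.0] * 6 + [39.0] * 55
        labels = [1] * 30 + [0] * 1 + [1] * 6 + [0] * 55
        conf = confusion_at_cutoff(scores, labels, 40.0)
        assert conf.sensitivity == pytest.approx(30 / 36)
        assert round(100 * conf.sensitivity, 1) == 83.3
        assert conf.ppv == pytest.approx(30 / 31)
        assert round(100 * conf.ppv, 1) == 96.8

    def test_undefined_ppv_absent(self):
        conf = confusion_at_cutoff([1.0, 2.0], [1, 0], 10.0)
        assert conf.ppv is None
        assert conf.npv == pytest.approx(0.5)

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_closure(self, data):
        n = data.draw(st.integers(1, 40))
        scores = data.draw(st.lists(st.floats(0, 100), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        cut = data.draw(st.floats(0, 100))
        conf = confusion_at_cutoff(scores, labels, cut)
        assert conf.tp + conf.fp + conf.fn + conf.tn == n
        assert conf.accuracy == pytest.approx((conf.tp + conf.tn) / n)
        for metric in (conf.sensitivity, conf.specificity, conf.ppv, conf.npv):
            if metric is not None:
                assert 0.0 <= metric <= 1.0


class TestBlandAltman:
    def test_identical_measurements(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == res.loa_low == res.loa_high == 0.0

    def test_hand_computed_sd(self):
        # differences {-1, +1}: mean 0, sd (n-1 denominator) = sqrt(2)
        res = bland_altman([0.0, 1.0], [1.0, 0.0])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96 * math.sqrt(2))
        assert res.loa_low == pytest.approx(-1.96 * math.sqrt(2))

    def test_constant_offset_orientation(self):
        x = np.array([10.0, 20.0, 30.0])
        res = bland_altman(x, x + 5)
        assert res.bias == pytest.approx(-5.0)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
    @settings(deadline=None)
    def test_antisymmetry(self, x):
        y = [v + 1.5 for v in x]
        ab = bland_altman(x, y)
        ba = bland_altman(y, x)
        assert ab.bias == pytest.approx(-ba.bias, abs=1e-9)
        assert ab.loa_low == pytest.approx(-ba.loa_high, abs=1e-9)
        assert ab.loa_high == pytest.approx(-ba.loa_low, abs=1e-9)


class TestIcc:
    def test_perfect_agreement(self):
        table = np.column_stack([np.arange(5.0), np.arange(5.0)])
        icc, (lo, hi), f = icc_absolute_agreement(table)
        assert icc == pytest.approx(1.0)

    def test_offset_penalized(self):
        base = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        icc, _, _ = icc_absolute_agreement(np.column_stack([base, base + 8]))
        assert icc < 1.0

    def test_toy_table_mean_squares(self):
        # hand arithmetic: MSR = 2.8, MSC = 85.333..., MSE = 0.7333...
        table = [[9, 2], [5, 1], [8, 4], [6, 1], [8, 2], [7, 1]]
        icc, (lo, hi), f = icc_absolute_agreement(table)
        msr, msc, mse = 2.8, 256 / 3, 11 / 15
        expected = (msr - mse) / (msr + mse + 2 * (msc - mse) / 6)
        assert icc == pytest.approx(expected, rel=1e-9)
        assert f == pytest.approx(msr / mse, rel=1e-9)

    def test_matches_pingouin_icc_a1(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        base = rng.normal(50, 15, 12)
        table = np.column_stack(
            [base + rng.normal(0, 5, 12), base + rng.normal(0, 5, 12)]
        )
        icc, (lo, hi), f = icc_absolute_agreement(table)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": list(range(2)) * 12,
                "score": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        assert lo == pytest.approx(row["CI95"][0], abs=0.01)
        assert hi == pytest.approx(row["CI95"][1], abs=0.01)

    def test_incomplete_design(self):
        with pytest.raises(IncompleteDesignError):
            icc_absolute_agreement([[1.0, 2.0], [3.0, float("nan")], [4.0, 5.0]])
        with pytest.raises(IncompleteDesignError):
            icc_absolute_agreement([[1.0, 2.0], [3.0, 4.0]])  # n < 3


class TestCorrelations:
    def test_exact_linear_map(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, rho = correlations(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, rho = correlations(x, x[::-1])
        assert r == pytest.approx(-1.0)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_scipy_midranks(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0]
        y = [2.7, 1.8, 2.8, 1.8, 4.6, 9.0, 4.5, 2.3, 6.0, 6.2]
        r, rho = correlations(x, y)
        assert r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_zero_variance(self):
        with pytest.raises(UndefinedCorrelationError):
            correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.data())
    @settings(deadline=None, max_examples=50)
    def test_matches_scipy_on_random_data(self, data):
        n = data.draw(st.integers(3, 30))
        x = data.draw(st.lists(st.integers(-10, 10).map(float), min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(-10, 10).map(float), min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        r, rho = correlations(x, y)
        assert r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-10)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-10)


class TestFisher:
    def test_table2_mvo_row(self):
        # the reported p for this table is 0.03; exact enumeration gives 0.040
        p = fisher_exact_2x2([[4, 17], [6, 4]])
        assert p == pytest.approx(0.04010688091550886, abs=1e-12)
        assert 0.02 <= p <= 0.05

    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_extreme_table(self):
        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_scipy_and_transposition(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-10)
        assert p == pytest.approx(fisher_exact_2x2([[a, c], [b, d]]), abs=1e-12)

    def test_chi2_no_correction(self):
        p = chi2_2x2([[4, 17], [6, 4]])
        ref = sps.chi2_contingency([[4, 17], [6, 4]], correction=False)[1]
        assert p == pytest.approx(ref, abs=1e-12)


def _panel(lesion_id, timepoint, imr, imr_angio):
    return IndexPanel(
        lesion_id=lesion_id, timepoint=timepoint,
        IMR=imr, IMR_angio=imr_angio, PdPa_hyp=0.9,
    )


class TestResponders:
    def _paired(self, post_imr, post_angio):
        n = len(post_imr)
        pre = [_panel(f"P{i}", "pre_pci", 50.0, 50.0) for i in range(n)]
        post = [
            _panel(f"P{i}", "post_pci", post_imr[i], post_angio[i]) for i in range(n)
        ]
        return pre, post

    def test_one_discordant_of_33(self):
        post_imr = [30.0] * 20 + [50.0] * 13
        post_angio = [30.0] * 21 + [50.0] * 12  # patient 20 disagrees
        pre, post = self._paired(post_imr, post_angio)
        res = classify_responders(pre, post, threshold=40.0)
        assert res.n_discordant == 1
        assert res.misclassification_rate == pytest.approx(1 / 33)
        assert round(100 * res.misclassification_rate, 0) == 3.0

    def test_strict_threshold_semantics(self):
        pre, post = self._paired([39.9] * 4, [39.9] * 4)
        res = classify_responders(pre, post)
        assert set(res.labels_imr) == {"good"}
        pre, post = self._paired([40.0] * 4, [40.0] * 4)
        res = classify_responders(pre, post)
        assert set(res.labels_imr) == {"partial_poor"}

    def test_unpaired_patients_rejected(self):
        pre, post = self._paired([30.0, 50.0], [30.0, 50.0])
        with pytest.raises(PairingError):
            classify_responders(pre[:1], post)
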