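"""Agreement statistics: ICC, Bland-Altman, ROC/Youden, confusion metrics,
Cohen's kappa — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radvital import (
    ConfusionTable,
    InsufficientDataError,
    InvalidArgumentError,
    PairedMeasurements,
    UndefinedStatisticError,
    bland_altman,
    cohens_kappa,
    confusion_metrics,
    icc_oneway,
    roc_youden,
)


def _anova_icc_oracle(a, b):
    """Brute-force one-way ANOVA variance components, k = 2 raters."""
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    msb = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    msw = np.sum((data - data.mean(axis=1, keepdims=True)) ** 2) / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def _auc_oracle(scores, labels):
    """Exhaustive pairwise concordance count, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


class TestICC:
    def test_perfect_agreement(self):
        result = icc_oneway(PairedMeasurements([1, 2, 3], [1, 2, 3]))
        assert result.icc == pytest.approx(1.0)
        assert result.ci_low <= result.icc <= result.ci_high

    def test_matches_anova_oracle(self):
        a = np.array([1.0, 3.0, 5.0, 7.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        result = icc_oneway(PairedMeasurements(a, b))
        assert result.icc == pytest.approx(_anova_icc_oracle(a, b), abs=1e-12)

    def test_matches_anova_oracle_on_random_data(self, rng):
        for _ in range(100):
            n = rng.integers(3, 15)
            a = rng.normal(size=n)
            b = a + rng.normal(scale=rng.uniform(0.1, 2.0), size=n)
            result = icc_oneway(PairedMeasurements(a, b))
            assert result.icc == pytest.approx(_anova_icc_oracle(a, b), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.normal(10, 2, size=12)
        b = a + rng.normal(0, 0.8, size=12)
        mine = icc_oneway(PairedMeasurements(a, b))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["A", "B"], 12),
            "score": np.column_stack([a, b]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].str.startswith(("ICC1", "ICC(1,1"))].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert mine.icc == pytest.approx(row["ICC"], abs=1e-6)
        # pingouin rounds the printed CI to 2 decimals
        assert mine.ci_low == pytest.approx(row[ci_col][0], abs=6e-3)
        assert min(mine.ci_high, 1.0) == pytest.approx(min(row[ci_col][1], 1.0), abs=6e-3)

    def test_constant_data_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_oneway(PairedMeasurements([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            icc_oneway(PairedMeasurements([1, 2], [1, 2]))

    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_location_scale_invariance(self, shift, scale):
        a = np.array([1.0, 2.5, 4.0, 5.0, 9.0])
        b = np.array([1.5, 2.0, 4.5, 5.5, 8.0])
        base = icc_oneway(PairedMeasurements(a, b)).icc
        moved = icc_oneway(PairedMeasurements(scale * a + shift, scale * b + shift)).icc
        assert moved == pytest.approx(base, abs=1e-8)

    def test_consistency_variant_matches_pingouin_icc3(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.normal(size=10)
        b = a + rng.normal(scale=0.5, size=10) + 1.0
        mine = icc_oneway(PairedMeasurements(a, b), variant="consistency")
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 2),
            "rater": np.tile(["A", "B"], 10),
            "score": np.column_stack([a, b]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].str.startswith(("ICC3", "ICC(C,1"))].iloc[0]
        assert mine.icc == pytest.approx(row["ICC"], abs=1e-6)


class TestBlandAltman:
    def test_identical_pairs(self):
        result = bland_altman(PairedMeasurements([1, 2, 3], [1, 2, 3]))
        assert result.bias == 0.0
        assert result.loa_low == 0.0
        assert result.loa_high == 0.0

    def test_alternating_differences(self):
        result = bland_altman(PairedMeasurements([1, -1, 1, -1], [0, 0, 0, 0]))
        sd = np.std([1, -1, 1, -1], ddof=1)
        assert result.bias == 0.0
        assert result.loa_high == pytest.approx(1.96 * sd)
        assert result.loa_low == pytest.approx(-1.96 * sd)

    def test_one_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman(PairedMeasurements([1.0], [2.0]))

    def test_loa_brackets_bias(self, rng):
        a = rng.normal(size=30)
        b = a + rng.normal(scale=0.5, size=30)
        result = bland_altman(PairedMeasurements(a, b))
        assert result.loa_low <= result.bias <= result.loa_high


class TestROCYouden:
    def test_perfect_separation(self):
        result = roc_youden(np.array([1, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1]))
        assert result.auc == 1.0
        thr = result.youden_threshold
        assert 3 < thr <= 10
        sens = [p[1] for p in result.points if p[0] == thr][0]
        spec = [p[2] for p in result.points if p[0] == thr][0]
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_auc_matches_concordance_oracle_small(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        result = roc_youden(scores, labels)
        assert result.auc == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)

    def test_auc_matches_exhaustive_oracle_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            result = roc_youden(scores, labels)
            assert result.auc == pytest.approx(_auc_oracle(scores, labels), abs=1e-10)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=40)
        labels = (rng.uniform(size=40) < 0.4).astype(int)
        result = roc_youden(scores, labels)
        assert result.auc == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_youden(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_points_ordered_by_threshold(self, rng):
        scores = rng.normal(size=20)
        labels = (rng.uniform(size=20) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        thresholds = [p[0] for p in roc_youden(scores, labels).points]
        assert thresholds == sorted(thresholds)


class TestConfusionMetrics:
    def test_printed_study_table(self):
        # 33 subjects: radar vs ECG at the 0.57 Hz threshold
        sens, spec, ccr = confusion_metrics(ConfusionTable(tp=14, fp=3, fn=0, tn=16))
        assert sens == 1.0
        assert spec == pytest.approx(16 / 19)  # 0.84 to 2 d.p.
        assert round(spec, 2) == 0.84
        assert ccr == pytest.approx(30 / 33)   # 0.909
        assert round(ccr, 3) == 0.909

    def test_perfect_table(self):
        assert confusion_metrics(ConfusionTable(1, 0, 0, 1)) == (1.0, 1.0, 1.0)

    def test_all_positives_missed(self):
        sens, spec, ccr = confusion_metrics(ConfusionTable(tp=0, fp=0, fn=5, tn=5))
        assert (sens, spec, ccr) == (0.0, 1.0, 0.5)

    def test_empty_margin_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            confusion_metrics(ConfusionTable(tp=3, fp=0, fn=2, tn=0))

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ConfusionTable(tp=-1, fp=0, fn=0, tn=1)


class TestCohensKappa:
    def test_printed_study_table(self):
        result = cohens_kappa(ConfusionTable(tp=14, fp=3, fn=0, tn=16))
        # p_o = 30/33, p_e = (17*14 + 16*19)/33^2
        p_o, p_e = 30 / 33, (17 * 14 + 16 * 19) / 33**2
        assert result.kappa == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)
        assert round(result.kappa, 3) == 0.819
        assert result.ci_high == 1.0  # capped
        assert result.ccr == pytest.approx(30 / 33)

    def test_perfect_diagonal(self):
        result = cohens_kappa(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        assert result.kappa == 1.0

    def test_independent_margins_give_zero(self):
        assert cohens_kappa(ConfusionTable(5, 5, 5, 5)).kappa == pytest.approx(0.0)

    def test_matches_sklearn_on_random_tables(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 20, size=4))
            if tp + fp + fn + tn == 0:
                continue
            table = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
            y_a = [1] * (tp + fp) + [0] * (fn + tn)
            y_b = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (tp + fp + fn + tn) ** 2
            if p_e == 1.0:
                with pytest.raises(UndefinedStatisticError):
                    cohens_kappa(table)
                continue
            assert cohens_kappa(table).kappa == pytest.approx(
                sk.cohen_kappa_score(y_a, y_b), abs=1e-10
            )

    def test_kappa_one_iff_no_off_diagonal(self, rng):
        for _ in range(20):
            tp, tn = (int(v) for v in rng.integers(1, 10, size=2))
            assert cohens_kappa(ConfusionTable(tp, 0, 0, tn)).kappa == 1.0
            assert cohens_kappa(ConfusionTable(tp, 1, 0, tn)).kappa < 1.0


class TestPairedMeasurementsValidation:
    def test_unequal_lengths(self):
        with pytest.raises(InvalidArgumentError):
            PairedMeasurements([1, 2, 3], [1, 2])

    def test_nonfinite(self):
        with pytest.raises(InvalidArgumentError):
            PairedMeasurements([1, np.nan], [1, 2])
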