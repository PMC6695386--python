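"""Agreement and diagnostic statistics for method-comparison studies.

Implements the toolkit used to validate a new measurement method against
a reference: one-way random-effects intraclass correlation (ICC(1,1))
with its F-based 95% CI, Bland-Altman bias and limits of agreement,
empirical ROC analysis with Youden's J threshold selection, confusion-
matrix metrics (sensitivity, specificity, correct classification rate)
and Cohen's kappa with a large-sample 95% CI.

Conventions: PeAF (the condition of interest) is the positive class;
limits of agreement use the 1.96 multiplier and the sample (n-1) SD;
the kappa CI upper bound is capped at 1.000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, InvalidArgumentError, UndefinedStatisticError


@dataclass
class PairedMeasurements:
    """Same-subject measurements by two methods, in subject order."""

    method_a: np.ndarray
    method_b: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float).ravel()
        self.method_b = np.asarray(self.method_b, dtype=float).ravel()
        if self.method_a.size != self.method_b.size:
            raise InvalidArgumentError("methods must have equal numbers of measurements")
        if self.method_a.size == 0:
            raise InvalidArgumentError("paired measurements must be non-empty")
        if not (np.all(np.isfinite(self.method_a)) and np.all(np.isfinite(self.method_b))):
            raise InvalidArgumentError("measurements must be finite")

    @property
    def n(self) -> int:
        return self.method_a.size


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float


@dataclass
class BAResult:
    bias: float
    loa_low: float
    loa_high: float


@dataclass
class ConfusionTable:
    """2x2 table with the condition of interest (e.g. PeAF) positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise InvalidArgumentError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))
        if self.total == 0:
            raise InvalidArgumentError("confusion table must have at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCResult:
    auc: float
    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    youden_threshold: float


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    ccr: float


def icc_oneway(pairs: PairedMeasurements, variant: str = "oneway") -> ICCResult:
    """ICC from a subjects-as-groups one-way ANOVA with two raters.

    Default ``variant="oneway"`` is ICC(1,1) — one-way random effects,
    single rater: ``(MSB - MSW) / (MSB + MSW)`` for k = 2, with the
    standard F-distribution 95% CI.  ``variant="consistency"`` gives the
    two-way mixed consistency coefficient ICC(3,1) instead.
    """
    if pairs.n < 3:
        raise InsufficientDataError(f"ICC needs >= 3 pairs, got {pairs.n}")
    data = np.column_stack([pairs.method_a, pairs.method_b])
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise UndefinedStatisticError("all measurements identical; ICC undefined (zero variance)")
    subject_means = data.mean(axis=1)
    ss_between = k * np.sum((subject_means - grand) ** 2)
    ss_within = np.sum((data - subject_means[:, None]) ** 2)
    msb = ss_between / (n - 1)

    if variant == "oneway":
        dfw = n * (k - 1)
        msw = ss_within / dfw
        if msb + (k - 1) * msw == 0:
            raise UndefinedStatisticError("zero total variance; ICC undefined")
        icc = (msb - msw) / (msb + (k - 1) * msw)
        if msw == 0:
            return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0)
        fobs = msb / msw
        f_u = stats.f.ppf(0.975, n - 1, dfw)
        f_l = stats.f.ppf(0.975, dfw, n - 1)
        fl = fobs / f_u
        fu = fobs * f_l
        ci_low = (fl - 1) / (fl + k - 1)
        ci_high = (fu - 1) / (fu + k - 1)
    elif variant == "consistency":
        rater_means = data.mean(axis=0)
        ss_rater = n * np.sum((rater_means - grand) ** 2)
        dfe = (n - 1) * (k - 1)
        mse = (ss_within - ss_rater) / dfe
        if msb + (k - 1) * mse == 0:
            raise UndefinedStatisticError("zero total variance; ICC undefined")
        icc = (msb - mse) / (msb + (k - 1) * mse)
        if mse == 0:
            return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0)
        fobs = msb / mse
        f_u = stats.f.ppf(0.975, n - 1, dfe)
        f_l = stats.f.ppf(0.975, dfe, n - 1)
        fl = fobs / f_u
        fu = fobs * f_l
        ci_low = (fl - 1) / (fl + k - 1)
        ci_high = (fu - 1) / (fu + k - 1)
    else:
        raise InvalidArgumentError(f"unknown ICC variant {variant!r}")
    return ICCResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(min(ci_high, 1.0)))


def bland_altman(pairs: PairedMeasurements) -> BAResult:
    """Bias and 95% limits of agreement: bias ± 1.96 x sample SD of a-b."""
    if pairs.n < 2:
        raise InsufficientDataError(f"Bland-Altman needs >= 2 pairs, got {pairs.n}")
    diff = pairs.method_a - pairs.method_b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BAResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def roc_youden(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Empirical ROC with AUC (Mann-Whitney, ties half) and Youden threshold.

    ``labels`` are binary truth (1 = positive); a subject is called
    positive when its score >= threshold.  Candidate thresholds are the
    midpoints between consecutive distinct scores plus outer sentinels;
    ties in Youden's J resolve to the lower threshold.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size or scores.size == 0:
        raise InvalidArgumentError("scores and labels must be non-empty and equal-length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("both classes must be present for ROC analysis")

    ranks = stats.rankdata(scores)  # mid-ranks count ties half
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    uniq = np.unique(scores)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    points = []
    best_j, best_thr = -np.inf, thresholds[0]
    for thr in thresholds:
        pred = scores >= thr
        sens = float(np.sum(pred & (labels == 1)) / n_pos)
        spec = float(np.sum(~pred & (labels == 0)) / n_neg)
        points.append((float(thr), sens, spec))
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_thr = j, float(thr)
    return ROCResult(auc=float(auc), points=points, youden_threshold=best_thr)


def confusion_metrics(table: ConfusionTable) -> tuple[float, float, float]:
    """(sensitivity, specificity, correct classification rate)."""
    if table.tp + table.fn == 0 or table.tn + table.fp == 0:
        raise UndefinedStatisticError("both condition-present and -absent margins must be nonzero")
    sens = table.tp / (table.tp + table.fn)
    spec = table.tn / (table.tn + table.fp)
    ccr = (table.tp + table.tn) / table.total
    return float(sens), float(spec), float(ccr)


def cohens_kappa(table: ConfusionTable) -> KappaResult:
    """Chance-corrected agreement with large-sample 95% CI (upper cap 1.000).

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the marginal products;
    SE = sqrt(p_o (1 - p_o) / n) / (1 - p_e).
    """
    n = table.total
    p_o = (table.tp + table.tn) / n
    row_pos = table.tp + table.fp  # method A calls positive
    row_neg = table.fn + table.tn
    col_pos = table.tp + table.fn  # method B (reference) positive
    col_neg = table.fp + table.tn
    p_e = (row_pos * col_pos + row_neg * col_neg) / (n * n)
    if p_e == 1.0:
        raise UndefinedStatisticError("chance agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = np.sqrt(p_o * (1.0 - p_o) / n) / (1.0 - p_e)
    ci_low = kappa - 1.96 * se
    ci_high = min(kappa + 1.96 * se, 1.0)
    return KappaResult(kappa=float(kappa), ci_low=float(ci_low), ci_high=float(ci_high), ccr=float(p_o))
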