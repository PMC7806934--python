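"""Cohort-level screening statistics.

Group comparisons, ROC construction, the two-axis quadrant classifier over
(average marker intensity, % positive cells), and the full screening-metric
set — sensitivity, specificity, predictive values, accuracy, odds ratio
with Woolf confidence interval and the 2x2 chi-squared p-value.

The quadrant rule: a sample is screen-positive when its average intensity
is at or above the cut-off's x value OR its % positive cells is at or above
the y value; only the lower-left quadrant (both strictly below) is
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutoffPoint",
    "ConfusionTable",
    "ScreeningMetrics",
    "PUBLISHED_CUTOFFS",
    "compare_groups",
    "roc_curve",
    "quadrant_classify",
    "confusion_from_rates",
    "screening_metrics",
    "evaluate_cutoffs",
    "correlation_r2",
]


@dataclass(frozen=True)
class CutoffPoint:
    """A two-axis cut-off: intensity (x, grey units) and % positive (y)."""

    x_intensity: float
    y_pct: float
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.y_pct <= 100.0 and not math.isinf(self.y_pct):
            raise ValueError("y_pct must lie in [0, 100]")


#: The three published operating points on the (intensity, % positive) plane.
PUBLISHED_CUTOFFS = (
    CutoffPoint(63.50, 40.00, "A"),
    CutoffPoint(90.28, 53.34, "B"),
    CutoffPoint(117.20, 63.38, "C"),
)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screen outcome counts: rows = disease status, columns = test."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_diseased + self.n_healthy


@dataclass(frozen=True)
class ScreeningMetrics:
    """Derived screening-test metrics for one confusion table."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    odds_ratio: float
    or_ci_95: tuple[float, float]
    p_value: float
    table: ConfusionTable
    haldane_applied: bool = False

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_95[0],
            "or_ci_high": self.or_ci_95[1],
            "p_value": self.p_value,
            "tp": self.table.tp,
            "fn": self.table.fn,
            "tn": self.table.tn,
            "fp": self.table.fp,
            "haldane_applied": self.haldane_applied,
        }


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided independent-samples t-test (Welch by default).

    Returns ``(t_statistic, p_value)``. Identical groups give t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # zero variance in both groups with equal means
        return 0.0, 1.0
    return float(t), float(p)


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC for the rule score >= threshold.

    ``labels`` are 1 for diseased, 0 for healthy; both classes must be
    present. Returns one (threshold, sensitivity, specificity) row per
    distinct score, ordered from the strictest threshold down, plus the AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    thresholds = np.unique(s)[::-1]
    rows = []
    for thr in thresholds:
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        rows.append((thr, tp / n_pos, 1.0 - fp / n_neg))
    curve = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])
    # trapezoid over (FPR, TPR) with the (0,0) and (1,1) anchors
    fpr = np.concatenate([[0.0], 1.0 - curve["specificity"].to_numpy(), [1.0]])
    tpr = np.concatenate([[0.0], curve["sensitivity"].to_numpy(), [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


def quadrant_classify(sample, cut: CutoffPoint) -> str:
    """Classify one sample on the two-axis quadrant rule.

    ``sample`` may be any object or mapping with ``avg_intensity`` and
    ``pct_positive``. Returns ``"positive"`` (intensity >= x or pct >= y,
    bounds inclusive) or ``"negative"`` (both strictly below). Undefined
    statistics raise.
    """
    if isinstance(sample, Mapping):
        intensity, pct = sample["avg_intensity"], sample["pct_positive"]
    else:
        intensity, pct = sample.avg_intensity, sample.pct_positive
    if not (np.isfinite(intensity) and np.isfinite(pct)):
        raise ValueError("sample statistics are undefined")
    positive = intensity >= cut.x_intensity or pct >= cut.y_pct
    return "positive" if positive else "negative"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def confusion_from_rates(
    sensitivity: float,
    specificity: float,
    n_diseased: int,
    n_healthy: int,
) -> ConfusionTable:
    """Reconstruct the 2x2 from printed rates and group sizes.

    tp = round(sensitivity * n_diseased), tn = round(specificity *
    n_healthy), complements fill fn/fp; rounding is half-up. This is the
    canonical path from a published sensitivity/specificity pair back to
    counts.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_diseased < 0 or n_healthy < 0:
        raise ValueError("group sizes must be non-negative")
    tp = _round_half_up(sensitivity * n_diseased)
    tn = _round_half_up(specificity * n_healthy)
    return ConfusionTable(tp=tp, fn=n_diseased - tp, tn=tn, fp=n_healthy - tn)


def screening_metrics(table: ConfusionTable) -> ScreeningMetrics:
    """Full screening-metric set for a 2x2.

    Odds ratio = (tp*tn)/(fp*fn) with a Woolf 95% CI
    (log OR +/- 1.96 * sqrt(1/tp + 1/fp + 1/fn + 1/tn)); when any cell is
    zero a Haldane–Anscombe +0.5 is added to all four cells for the OR and
    CI (flagged). The p-value is a chi-squared test on the original table
    without continuity correction.
    """
    if table.n_diseased == 0 or table.n_healthy == 0:
        raise ValueError("both disease-status rows must be non-empty")
    if table.tp + table.fp == 0 or table.tn + table.fn == 0:
        raise ValueError("both test-result columns must be non-empty")
    tp, fn, tn, fp = table.tp, table.fn, table.tn, table.fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp)
    npv = tn / (tn + fn)
    accuracy = (tp + tn) / table.total
    cells = np.array([tp, fn, tn, fp], dtype=float)
    haldane = bool((cells == 0).any())
    if haldane:
        cells = cells + 0.5
    a, b, c, d = cells  # tp, fn, tn, fp
    odds_ratio = (a * c) / (b * d)
    se = math.sqrt((1 / cells).sum())
    log_or = math.log(odds_ratio)
    ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))
    chi2, p, _, _ = stats.chi2_contingency(
        np.array([[tp, fn], [fp, tn]]), correction=False
    )
    return ScreeningMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=accuracy,
        odds_ratio=float(odds_ratio),
        or_ci_95=ci,
        p_value=float(p),
        table=table,
        haldane_applied=haldane,
    )


def _tabulate(cohort: pd.DataFrame, cut: CutoffPoint) -> ConfusionTable:
    calls = cohort.apply(lambda row: quadrant_classify(row, cut), axis=1)
    diseased = cohort["group"] == "cancer"
    positive = calls == "positive"
    return ConfusionTable(
        tp=int((diseased & positive).sum()),
        fn=int((diseased & ~positive).sum()),
        tn=int((~diseased & ~positive).sum()),
        fp=int((~diseased & positive).sum()),
    )


def evaluate_cutoffs(
    cohort: pd.DataFrame,
    cuts: Iterable[CutoffPoint] = PUBLISHED_CUTOFFS,
    by_replicate: bool = False,
):
    """Quadrant-classify every sample and derive metrics per cut-off.

    ``cohort`` needs columns ``group`` (cancer/normal), ``avg_intensity``,
    ``pct_positive`` and, for ``by_replicate``, ``replicate_set``. Returns
    ``{cut_name: ScreeningMetrics}``, or with ``by_replicate`` a second
    nested dict ``{cut_name: {replicate_set: ScreeningMetrics}}``.
    """
    required = {"group", "avg_intensity", "pct_positive"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    groups = set(cohort["group"])
    if not {"cancer", "normal"} <= groups:
        raise ValueError("cohort must contain both cancer and normal samples")
    cuts = list(cuts)
    overall = {}
    for i, cut in enumerate(cuts):
        name = cut.name or f"cut{i + 1}"
        overall[name] = screening_metrics(_tabulate(cohort, cut))
    if not by_replicate:
        return overall
    if "replicate_set" not in cohort.columns:
        raise ValueError("by_replicate requires a replicate_set column")
    per_rep: dict[str, dict] = {}
    for i, cut in enumerate(cuts):
        name = cut.name or f"cut{i + 1}"
        per_rep[name] = {
            rep: screening_metrics(_tabulate(sub, cut))
            for rep, sub in cohort.groupby("replicate_set")
            if {"cancer", "normal"} <= set(sub["group"])
        }
    return overall, per_rep


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two paired statistics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired data with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
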