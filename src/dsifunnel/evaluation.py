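"""Confusion matrices, diagnostic metrics and distribution summaries.

Metric conventions (fixed by the published worked examples):

* confusion matrices store ``counts[predicted_row][actual_column]``;
* overall accuracy = trace / total ("share of correct diagnoses");
* per-class sensitivity = diagonal / actual-column total;
* per-class specificity = fraction of non-class actuals correctly
  *not* assigned to the class;
* eligibility sensitivity = selected eligible / all eligible,
  specificity = rejected ineligible / all ineligible.

Letter-value summaries (median, fourths, eighths, sixteenths by
repeated median-halving) describe DSI distributions per diagnostic
group, as an alternative to boxplots for larger samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import reference_tables as ref
from .cohort import (
    Cohort,
    DiagnosisLabel,
    INDETERMINATE,
    eligible_ground_truth,
    syndrome_of,
)
from .scenarios import ELIGIBLE, NO_DIAGNOSIS, NOT_ELIGIBLE, TrajectoryResult

__all__ = [
    "ConfusionMatrix",
    "LetterValueSummary",
    "confusion",
    "overall_accuracy",
    "class_sensitivity",
    "class_specificity",
    "eligibility_metrics",
    "letter_value_summary",
    "letter_values_by_group",
    "round_half_up",
    "reproduce_reference_tables",
    "KNOWN_ANOMALIES",
    "syndrome_confusion",
    "etiology_confusion",
    "eligibility_confusion",
]


def round_half_up(x: float, places: int = 2) -> float:
    """Display rounding: half-up (0.725 -> 0.73), not banker's."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Count matrix with actual diagnoses in columns, predictions in rows."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape must match label count")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"label {label!r} not in {self.labels}") from exc

    def actual_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def predicted_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(self.labels, name="predicted"),
                            columns=pd.Index(self.labels, name="actual"))


def confusion(true_labels: Sequence, predicted_labels: Sequence,
              label_order: Sequence) -> ConfusionMatrix:
    """Tally aligned (actual, predicted) pairs into a ConfusionMatrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must align")
    labels = tuple(label_order)
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in idx or p not in idx:
            raise KeyError(f"label outside order: actual={t!r} predicted={p!r}")
        counts[idx[p], idx[t]] += 1
    return ConfusionMatrix(labels, counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def class_sensitivity(cm: ConfusionMatrix, label) -> Optional[float]:
    """Diagonal over actual-column total; None when the class is absent."""
    i = cm._index(label)
    denom = cm.actual_totals()[i]
    return None if denom == 0 else float(cm.counts[i, i]) / float(denom)


def class_specificity(cm: ConfusionMatrix, label) -> Optional[float]:
    """Non-class actuals correctly not assigned to the class."""
    i = cm._index(label)
    non_class = cm.total - cm.actual_totals()[i]
    if non_class == 0:
        return None
    false_pos = cm.predicted_totals()[i] - cm.counts[i, i]
    return float(non_class - false_pos) / float(non_class)


def eligibility_metrics(cm: ConfusionMatrix) -> tuple:
    """(sensitivity, specificity) of a 2x2 eligibility selection matrix.

    Convention: labels ordered (not eligible, eligible); sensitivity =
    selected eligible / all eligible, specificity = rejected ineligible
    / all ineligible.  Zero denominators yield None.
    """
    if len(cm.labels) != 2:
        raise ValueError("expected a 2x2 eligibility matrix")
    eligible_total = cm.actual_totals()[1]
    ineligible_total = cm.actual_totals()[0]
    sens = None if eligible_total == 0 else float(cm.counts[1, 1]) / float(eligible_total)
    spec = None if ineligible_total == 0 else float(cm.counts[0, 0]) / float(ineligible_total)
    return sens, spec


# ---------------------------------------------------------------------------
# letter values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LetterValueSummary:
    """Nested quantile boxes: median, fourths (F), eighths (E), sixteenths (D)."""

    group: object
    median: float
    fourths: tuple
    eighths: tuple
    sixteenths: tuple
    count: int

    def nested(self) -> bool:
        f, e, d = self.fourths, self.eighths, self.sixteenths
        return (e[0] <= f[0] <= self.median <= f[1] <= e[1]
                and d[0] <= e[0] and e[1] <= d[1])


def _value_at_depth(sorted_vals: np.ndarray, depth: float, from_top: bool) -> float:
    vals = sorted_vals[::-1] if from_top else sorted_vals
    k = int(math.floor(depth))
    if depth == k:
        return float(vals[k - 1])
    return float((vals[k - 1] + vals[k]) / 2.0)


def letter_value_summary(values: Sequence[float], group: object = None) -> LetterValueSummary:
    """Letter values by repeated median-halving down to sixteenths.

    Depths follow the classic rule d1 = (n+1)/2, d_{k+1} =
    (floor(d_k)+1)/2, so 1..16 gives median 8.5 and fourths (4.5, 12.5).
    """
    vals = np.sort(np.asarray(values, dtype=float))
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    if n == 0:
        raise ValueError("empty group")
    depths = []
    d = (n + 1) / 2.0
    for _ in range(4):  # median, fourths, eighths, sixteenths
        depths.append(d)
        d = (math.floor(d) + 1) / 2.0
    med = _value_at_depth(vals, depths[0], from_top=False)
    pairs = [
        (_value_at_depth(vals, depth, False), _value_at_depth(vals, depth, True))
        for depth in depths[1:]
    ]
    return LetterValueSummary(group, med, pairs[0], pairs[1], pairs[2], n)


def letter_values_by_group(values_by_group: Mapping) -> list[LetterValueSummary]:
    return [letter_value_summary(v, group=g) for g, v in values_by_group.items() if len(v)]


def plot_letter_values(summaries: Sequence[LetterValueSummary], path,
                       title: str = "DSI distribution") -> None:
    """Render nested letter-value boxes to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(summaries) + 2, 4))
    widths = {"fourths": 0.6, "eighths": 0.4, "sixteenths": 0.25}
    for i, s in enumerate(summaries):
        for attr, w in widths.items():
            lo, hi = getattr(s, attr)
            ax.add_patch(plt.Rectangle((i - w / 2, lo), w, hi - lo,
                                       fill=True, alpha=0.35, color="C0"))
        ax.plot([i - 0.35, i + 0.35], [s.median, s.median], color="k")
    ax.set_xticks(range(len(summaries)))
    ax.set_xticklabels([str(s.group) for s in summaries])
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# trajectory -> matrices
# ---------------------------------------------------------------------------


def syndrome_confusion(trajectories: Sequence[TrajectoryResult],
                       cohort: Cohort) -> ConfusionMatrix:
    """CN/MCI/DEM matrix of final syndrome outcomes vs clinical syndrome.

    Trajectories ending without a syndrome label are excluded (they are
    counted separately by the funnel summary).
    """
    actual, predicted = [], []
    for t in trajectories:
        if t.outcome not in ("CN", "MCI", "DEM"):
            continue
        actual.append(syndrome_of(cohort[t.patient_id].diagnosis))
        predicted.append(t.outcome)
    return confusion(actual, predicted, ("CN", "MCI", "DEM"))


def etiology_confusion(trajectories: Sequence[TrajectoryResult],
                       cohort: Cohort) -> tuple:
    """(matrix over diagnosed patients, number with "no diagnosis").

    Labels CN + the four etiologies, mirroring the published combined
    matrix; patients still undiagnosed after CSF are excluded from the
    matrix and returned as a count.
    """
    labels = ("CN", "AD", "FTD", "VaD", "DLB")
    actual, predicted = [], []
    undiagnosed = 0
    for t in trajectories:
        if t.outcome == NO_DIAGNOSIS:
            undiagnosed += 1
            continue
        actual.append(cohort[t.patient_id].diagnosis.value)
        predicted.append(t.outcome)
    return confusion(actual, predicted, labels), undiagnosed


def eligibility_confusion(trajectories: Sequence[TrajectoryResult],
                          cohort: Cohort) -> ConfusionMatrix:
    """2x2 predicted-vs-true eligibility; indeterminate truth excluded."""
    actual, predicted = [], []
    for t in trajectories:
        truth = eligible_ground_truth(cohort[t.patient_id])
        if truth is INDETERMINATE:
            continue
        actual.append("eligible" if truth else "not eligible")
        predicted.append("eligible" if t.outcome == ELIGIBLE else "not eligible")
    return confusion(actual, predicted, ("not eligible", "eligible"))


# ---------------------------------------------------------------------------
# reproduction of the published reference tables
# ---------------------------------------------------------------------------

#: (table, metric) pairs where the printed value is internally
#: inconsistent with the printed matrix; documented in reference_tables.
KNOWN_ANOMALIES = frozenset({
    ("syndrome_1a", "sensitivity.CN"),
    ("syndrome_1a", "specificity.CN"),
    ("syndrome_1b_step1", "sensitivity.CN"),
    ("syndrome_1b_step1", "specificity.CN"),
    ("syndrome_1b_combined", "sensitivity.CN"),
    ("syndrome_1b_combined", "specificity.CN"),
    ("syndrome_1b_combined", "accuracy"),
    ("etiology_combined", "specificity.CN"),
    ("etiology_combined", "specificity.AD"),
    ("etiology_combined", "specificity.FTD"),
    ("etiology_combined", "specificity.DLB"),
    ("eligibility_combined", "specificity"),
})


def _matrix(table: dict) -> ConfusionMatrix:
    return ConfusionMatrix(table["labels"], np.asarray(table["counts"]))


def reproduce_reference_tables() -> pd.DataFrame:
    """Recompute every derivable printed metric from the embedded matrices.

    Returns a report with columns (table, metric, computed, printed,
    status); status is ``ok`` when the half-up 2-decimal rounding of the
    recomputation equals the printed value, ``anomaly`` for the
    documented printing inconsistencies, and ``MISMATCH`` otherwise
    (a MISMATCH indicates a defect in the metric implementations).
    """
    rows = []

    def check(table_name: str, metric: str, computed: float, printed: float):
        ok = round_half_up(computed, 2) == printed
        if ok:
            status = "ok"
        elif (table_name, metric) in KNOWN_ANOMALIES:
            status = "anomaly"
        else:
            status = "MISMATCH"
        rows.append({
            "table": table_name, "metric": metric,
            "computed": round_half_up(computed, 4), "printed": printed,
            "status": status,
        })

    for name, table in (
        ("syndrome_1a", ref.SYNDROME_1A),
        ("syndrome_1b_step1", ref.SYNDROME_1B_STEP1),
        ("syndrome_1b_combined", ref.SYNDROME_1B_COMBINED),
        ("etiology_combined", ref.ETIOLOGY_COMBINED),
    ):
        cm = _matrix(table)
        check(name, "accuracy", overall_accuracy(cm), table["printed"]["accuracy"])
        for label in table["labels"]:
            check(name, f"sensitivity.{label}", class_sensitivity(cm, label),
                  table["printed"]["sensitivity"][label])
            check(name, f"specificity.{label}", class_specificity(cm, label),
                  table["printed"]["specificity"][label])

    cm5 = _matrix(ref.ELIGIBILITY_COMBINED)
    sens, spec = eligibility_metrics(cm5)
    check("eligibility_combined", "sensitivity", sens,
          ref.ELIGIBILITY_COMBINED["printed"]["sensitivity"])
    check("eligibility_combined", "specificity", spec,
          ref.ELIGIBILITY_COMBINED["printed"]["specificity"])

    t6 = np.asarray(ref.ELIGIBLE_AD_SUBTYPES["counts"], dtype=float)
    for j, label in enumerate(ref.ELIGIBLE_AD_SUBTYPES["labels"]):
        detected = t6[0, j] / (t6[0, j] + t6[1, j])
        check("eligible_ad_subtypes", f"sensitivity.{label}", detected,
              ref.ELIGIBLE_AD_SUBTYPES["printed"]["sensitivity"][label])

    # funnel counts quoted in the running text
    cm1a = _matrix(ref.SYNDROME_1A)
    pred = dict(zip(cm1a.labels, cm1a.predicted_totals()))
    for label, printed_n in ref.TEXT_COUNTS["syndrome_1a_classified"].items():
        check("syndrome_1a", f"classified_n.{label}", pred[label], printed_n)
    cm1b1 = _matrix(ref.SYNDROME_1B_STEP1)
    check("syndrome_1b_step1", "indeterminate_n",
          cm1b1.predicted_totals()[1], ref.TEXT_COUNTS["syndrome_1b_step1_indeterminate"])
    cm1bc = _matrix(ref.SYNDROME_1B_COMBINED)
    check("syndrome_1b_combined", "mri_n",
          cm1bc.predicted_totals()[1] + cm1bc.predicted_totals()[2],
          ref.TEXT_COUNTS["syndrome_1b_mri_n"])
    cmE = _matrix(ref.ETIOLOGY_COMBINED)
    check("etiology_combined", "diagnosed_n", cmE.total,
          ref.TEXT_COUNTS["etiology_diagnosed_n"])
    check("eligibility_combined", "eligible_total",
          cm5.actual_totals()[1], ref.TEXT_COUNTS["eligibility_total_eligible"])
    check("eligibility_combined", "selected_true_positive",
          cm5.counts[1, 1], ref.TEXT_COUNTS["eligibility_selected_true_positive"])

    return pd.DataFrame(rows)
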