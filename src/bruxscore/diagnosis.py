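"""Diagnostic cut-off and screening accuracy.

A subject screens positive when their bruxism index is strictly greater
than the cut-off (default 2 SB episodes per hour). Device calls are
cross-tabulated against the clinical reference standard (symptomatic
examination plus positive self-report) into a 2x2 confusion table, from
which sensitivity = 100*TP/(TP+FN) and specificity = 100*TN/(TN+FP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-table cells must be non-negative")

    @property
    def clinical_positives(self) -> int:
        return self.tp + self.fn

    @property
    def clinical_negatives(self) -> int:
        return self.fp + self.tn


@dataclass
class DiagnosticAccuracy:
    sensitivity: float | None   # %, None when no clinical positives
    specificity: float | None   # %, None when no clinical negatives
    table: ConfusionTable


def diagnose(index: float, cutoff: float = 2.0) -> str:
    """Positive iff the bruxism index strictly exceeds the cut-off."""
    if index < 0:
        raise ValueError("bruxism index cannot be negative")
    return POSITIVE if index > cutoff else NEGATIVE


def confusion_table(
    device_calls: Sequence[str], clinical_labels: Sequence[str]
) -> ConfusionTable:
    """Cross-tabulate device calls against the clinical reference."""
    if len(device_calls) != len(clinical_labels):
        raise ValueError("device calls and clinical labels must pair up")
    valid = (POSITIVE, NEGATIVE)
    tp = fn = fp = tn = 0
    for dev, clin in zip(device_calls, clinical_labels):
        if dev not in valid or clin not in valid:
            raise ValueError(f"unknown label in pair ({dev!r}, {clin!r})")
        if clin == POSITIVE:
            tp += dev == POSITIVE
            fn += dev == NEGATIVE
        else:
            fp += dev == POSITIVE
            tn += dev == NEGATIVE
    return ConfusionTable(tp, fn, fp, tn)


def sensitivity(table: ConfusionTable) -> float:
    """100 * TP / (TP + FN); undefined without clinical positives."""
    denom = table.tp + table.fn
    if denom == 0:
        raise ZeroDivisionError("sensitivity undefined: no clinical positives")
    return 100.0 * table.tp / denom


def specificity(table: ConfusionTable) -> float:
    """100 * TN / (TN + FP); undefined without clinical negatives."""
    denom = table.tn + table.fp
    if denom == 0:
        raise ZeroDivisionError("specificity undefined: no clinical negatives")
    return 100.0 * table.tn / denom


def accuracy_from_calls(
    device_calls: Sequence[str], clinical_labels: Sequence[str]
) -> DiagnosticAccuracy:
    table = confusion_table(device_calls, clinical_labels)
    return DiagnosticAccuracy(
        sensitivity=sensitivity(table) if table.clinical_positives else None,
        specificity=specificity(table) if table.clinical_negatives else None,
        table=table,
    )


def cutoff_match_rate(indices: Sequence[float], cutoff: float = 2.0) -> float:
    """Percent of subjects whose index strictly exceeds the cut-off."""
    if len(indices) == 0:
        raise ValueError("empty group")
    return 100.0 * sum(x > cutoff for x in indices) / len(indices)


def clinical_reference(symptoms_present: bool, self_report_positive: bool) -> str:
    """The clinical reference standard: symptomatic AND self-reported."""
    return POSITIVE if (symptoms_present and self_report_positive) else NEGATIVE
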