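"""Group-fairness statistics for a binary protected attribute.

The protected attribute is binary gender coded 0 = female, 1 = male. Both
disparity statistics are signed female minus male:

* DPD (demographic parity difference) = selection_rate(F) - selection_rate(M)
* EOD (equal opportunity difference)  = TPR(F) - TPR(M)

A positive value therefore means the model flags (or correctly flags) female
patients more often. A group with no true positives has an undefined TPR;
that state is explicit (``tpr is None``) and propagates to an
:class:`UndefinedMetricError` from :func:`equal_opportunity_difference`,
never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "GroupMetrics",
    "FairnessReport",
    "UndefinedMetricError",
    "GROUP_LABELS",
    "group_confusion",
    "demographic_parity_difference",
    "equal_opportunity_difference",
    "fairness_report",
]

GROUP_LABELS = {0: "female", 1: "male"}


class UndefinedMetricError(ValueError):
    """A rate needed by the requested statistic is undefined (0/0)."""


@dataclass(frozen=True)
class GroupMetrics:
    """Confusion counts and rates for one protected group."""

    label: str
    n: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def selection_rate(self) -> float:
        return (self.tp + self.fp) / self.n

    @property
    def tpr(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def fpr(self) -> float | None:
        neg = self.fp + self.tn
        return self.fp / neg if neg else None

    def to_dict(self) -> dict:
        return {
            "group": self.label,
            "n": self.n,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "selection_rate": self.selection_rate,
            "TPR": self.tpr,
            "FPR": self.fpr,
        }


@dataclass(frozen=True)
class FairnessReport:
    """Per-group metrics plus the two headline disparities."""

    groups: dict[str, GroupMetrics]
    dpd: float
    eod: float
    threshold: float
    n: int

    def to_dict(self) -> dict:
        return {
            "groups": {k: v.to_dict() for k, v in self.groups.items()},
            "DPD": self.dpd,
            "EOD": self.eod,
            "threshold": self.threshold,
            "n": self.n,
        }


def _as_arrays(y_true, y_pred, group):
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    group = np.asarray(group, dtype=np.int64)
    if not (len(y_true) == len(y_pred) == len(group)):
        raise ValueError("y_true, y_pred and group must have equal length")
    return y_true, y_pred, group


def group_confusion(y_true, y_pred, group) -> dict[str, GroupMetrics]:
    """Exact confusion counts per protected group (0 = female, 1 = male)."""
    y_true, y_pred, group = _as_arrays(y_true, y_pred, group)
    out: dict[str, GroupMetrics] = {}
    for g, label in GROUP_LABELS.items():
        mask = group == g
        if not mask.any():
            continue
        t, p = y_true[mask], y_pred[mask]
        out[label] = GroupMetrics(
            label=label,
            n=int(mask.sum()),
            tp=int(((t == 1) & (p == 1)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
            tn=int(((t == 0) & (p == 0)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
        )
    return out


def _require_groups(groups: Mapping[str, GroupMetrics]):
    missing = [lbl for lbl in GROUP_LABELS.values() if lbl not in groups]
    if missing:
        raise ValueError(f"group(s) {missing} absent from the data")


def demographic_parity_difference(y_true, y_pred, group) -> float:
    """Selection-rate difference, female minus male."""
    groups = group_confusion(y_true, y_pred, group)
    _require_groups(groups)
    return groups["female"].selection_rate - groups["male"].selection_rate


def equal_opportunity_difference(y_true, y_pred, group) -> float:
    """TPR difference, female minus male.

    Raises :class:`UndefinedMetricError` if either group has no true
    positives.
    """
    groups = group_confusion(y_true, y_pred, group)
    _require_groups(groups)
    undefined = [lbl for lbl in ("female", "male") if groups[lbl].tpr is None]
    if undefined:
        raise UndefinedMetricError(
            f"TPR undefined for group(s) {undefined}: no true positives"
        )
    return groups["female"].tpr - groups["male"].tpr


def fairness_report(y_true, y_pred, group, threshold: float = 0.5) -> FairnessReport:
    """Full per-group report plus DPD and EOD at the given threshold."""
    groups = group_confusion(y_true, y_pred, group)
    _require_groups(groups)
    return FairnessReport(
        groups=groups,
        dpd=demographic_parity_difference(y_true, y_pred, group),
        eod=equal_opportunity_difference(y_true, y_pred, group),
        threshold=threshold,
        n=int(len(np.asarray(y_true))),
    )
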