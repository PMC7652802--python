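"""One-rule cut-point learning on model-estimated parameters and DDI
category assignment.

A CYP3A interaction can be read off a single midazolam profile by placing
the model-estimated midazolam metabolic clearance (Q_met, L/h) into one of
three ordered windows: inhibition (low), no modulation (middle), induction
(high).  The two thresholds are learned with a one-level decision tree
("OneR"-style): an exhaustive search over all pairs of candidate
cut-points that maximizes training accuracy.  The published thresholds
(16.4 and 41.8 L/h) ship as ``paper_cutpoints.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import load_cutpoints_json

__all__ = [
    "ORDERED_LABELS",
    "CutPointModel",
    "ConfusionSummary",
    "learn_cutpoints",
    "classify",
    "evaluate_classification",
    "paper_cutpoints",
    "collapse_inhibition",
]

#: ordered category labels, low to high parameter value
ORDERED_LABELS = ("inhibition", "no_modulation", "induction")


def collapse_inhibition(categories: Sequence[str]) -> np.ndarray:
    """Map treatment-arm categories onto the three classifier labels.

    Reversible and irreversible inhibition collapse to ``inhibition``;
    ``constitutive`` maps to ``no_modulation``.
    """
    mapping = {
        "constitutive": "no_modulation",
        "no_modulation": "no_modulation",
        "reversible_inhibition": "inhibition",
        "irreversible_inhibition": "inhibition",
        "inhibition": "inhibition",
        "induction": "induction",
    }
    return np.array([mapping[c] for c in categories])


@dataclass(frozen=True)
class CutPointModel:
    """Two thresholds splitting a parameter range into three DDI classes.

    The intervals are half-open: value < ``t_low`` -> inhibition;
    ``t_low`` <= value < ``t_high`` -> no modulation; value >= ``t_high``
    -> induction (a value exactly at a threshold falls in the lower
    class's upper neighbour, i.e. thresholds belong to the interval above).
    """

    parameter_name: str = "Qmet"
    t_low: float = 16.4
    t_high: float = 41.8
    labels: tuple[str, str, str] = ORDERED_LABELS
    training_accuracy: float | None = None

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError(f"t_low must be < t_high, got {self.t_low}, {self.t_high}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CutPointModel":
        d = json.loads(Path(path).read_text())
        d = {k: d[k] for k in ("parameter_name", "t_low", "t_high", "labels",
                               "training_accuracy") if k in d}
        if "labels" in d:
            d["labels"] = tuple(d["labels"])
        return cls(**d)


def paper_cutpoints() -> CutPointModel:
    """The published Q_met cut-point model (16.4 / 41.8 L/h)."""
    d = load_cutpoints_json()
    return CutPointModel(
        parameter_name=d["parameter_name"], t_low=d["t_low"], t_high=d["t_high"],
        labels=tuple(d["labels"]), training_accuracy=d.get("training_accuracy"),
    )


def classify(values, model: CutPointModel) -> np.ndarray:
    """Assign each parameter value to an ordered DDI category."""
    v = np.asarray(values, dtype=float)
    lo, mid, hi = model.labels
    out = np.where(v < model.t_low, lo, np.where(v < model.t_high, mid, hi))
    return out


def _accuracy(values: np.ndarray, labels: np.ndarray, t_low: float, t_high: float,
              ordered: tuple[str, str, str]) -> float:
    pred = np.where(values < t_low, ordered[0],
                    np.where(values < t_high, ordered[1], ordered[2]))
    return float(np.mean(pred == labels))


def learn_cutpoints(
    values: Sequence[float],
    labels: Sequence[str],
    parameter_name: str = "Qmet",
) -> CutPointModel:
    """Learn the two thresholds maximizing training accuracy.

    A one-level decision tree on a single numeric attribute: candidate
    thresholds are the midpoints between consecutive sorted unique values
    and every ordered threshold pair is scored; ties break toward the
    smallest ``(t_low, t_high)``, making the result deterministic.  The
    three classes are assigned to the intervals by their label medians
    (lowest median -> lowest interval).  Every class must be represented.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    classes, counts = np.unique(lab, return_counts=True)
    if len(classes) != 3:
        raise ValueError(
            f"need exactly the 3 classes {ORDERED_LABELS}, got {list(classes)}"
        )
    medians = {c: float(np.median(v[lab == c])) for c in classes}
    ordered = tuple(sorted(classes, key=lambda c: medians[c]))
    uniq = np.unique(v)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    if cands.size < 2:
        raise ValueError("not enough distinct values to place two thresholds")
    # score all ordered pairs (vectorized over the pair grid)
    n = v.size
    order = np.argsort(v, kind="stable")
    vs, ls = v[order], lab[order]
    # counts of each ordered class among obs below each candidate index
    below = np.searchsorted(vs, cands, side="left")  # obs strictly below cand
    cum = {
        c: np.concatenate([[0], np.cumsum(ls == c)]) for c in ordered
    }
    best = None
    for i, t_low in enumerate(cands):
        n_lo = cum[ordered[0]][below[i]]
        # correct among middle/upper depend on t_high
        j_range = range(i + 1, cands.size)
        for j in j_range:
            n_mid = cum[ordered[1]][below[j]] - cum[ordered[1]][below[i]]
            n_hi = (cum[ordered[2]][n] - cum[ordered[2]][below[j]])
            acc = (n_lo + n_mid + n_hi) / n
            key = (-acc, t_low, cands[j])
            if best is None or key < best[0]:
                best = (key, t_low, float(cands[j]), acc)
    _, t_low, t_high, acc = best
    return CutPointModel(
        parameter_name=parameter_name, t_low=float(t_low), t_high=float(t_high),
        labels=ordered, training_accuracy=float(acc),
    )


@dataclass
class ConfusionSummary:
    """3x3 confusion counts with the summary rates used for DDI screening."""

    counts: pd.DataFrame  # actual (rows) x predicted (columns)
    sensitivity: dict[str, float]  # per-class correct / actual
    specificity_no_modulation: float
    accuracy: float

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path)


def evaluate_classification(
    predicted: Sequence[str], actual: Sequence[str]
) -> ConfusionSummary:
    """Confusion matrix and summary rates of a categorical prediction.

    ``sensitivity[c]`` is the fraction of actual-class-``c`` cases
    predicted as ``c``; the specificity of DDI detection is the fraction
    of truly unmodulated cases classified as no modulation; accuracy is
    the trace over the total.
    """
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual must have equal length")
    counts = pd.DataFrame(
        0, index=list(ORDERED_LABELS), columns=list(ORDERED_LABELS), dtype=int
    )
    for a, p in zip(act, pred):
        counts.loc[a, p] += 1
    totals = counts.sum(axis=1)
    sens = {
        c: float(counts.loc[c, c] / totals[c]) if totals[c] else float("nan")
        for c in ORDERED_LABELS
    }
    acc = float(np.trace(counts.to_numpy()) / counts.to_numpy().sum())
    return ConfusionSummary(
        counts=counts,
        sensitivity=sens,
        specificity_no_modulation=sens["no_modulation"],
        accuracy=acc,
    )
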