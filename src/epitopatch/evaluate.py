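"""Evaluation protocol: prediction accuracy (precision over the predicted
set), ROC curves traced in steps of 1% of surface residues, and AUC."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .structure import ResidueId

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The metric has no value (empty prediction, or single-class labels)."""


def prediction_accuracy(predicted: set[ResidueId],
                        epitope: set[ResidueId]) -> float:
    """Correctly predicted epitopic residues over all predicted residues."""
    if not predicted:
        raise UndefinedMetricError("accuracy undefined for an empty prediction")
    return len(predicted & epitope) / len(predicted)


@dataclass(frozen=True)
class RocCurve:
    """Stepped ROC: (FPR, TPR) points from (0,0) to (1,1), trapezoidal AUC."""

    points: np.ndarray  # (k, 2) columns FPR, TPR

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.points[:, 1], self.points[:, 0]))

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def curve_from_sets(nested_sets: Iterable[set[ResidueId]],
                    epitope: set[ResidueId],
                    surface: Sequence[ResidueId]) -> RocCurve:
    """ROC from a nested family of predicted sets (smallest to largest)."""
    surface_set = set(surface)
    positives = epitope & surface_set
    negatives = surface_set - epitope
    if not positives or not negatives:
        raise UndefinedMetricError("need at least one epitopic and one "
                                   "non-epitopic surface residue")
    pts = [(0.0, 0.0)]
    for pred in nested_sets:
        tpr = len(pred & positives) / len(positives)
        fpr = len(pred & negatives) / len(negatives)
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    arr = np.array(pts, dtype=float)
    # nested inputs give monotone coordinates; guard against caller error
    if np.any(np.diff(arr, axis=0) < -1e-12):
        raise ValueError("prediction sets must be nested for a valid ROC")
    return RocCurve(arr)


def roc_from_ranking(ranking: Sequence[ResidueId],
                     epitope: set[ResidueId],
                     step_fraction: float = 0.01) -> RocCurve:
    """Grow the predicted set down the ranking in steps of ``step_fraction``
    of the surface (1% by default, at least one residue) and trace the ROC."""
    n = len(ranking)
    if n == 0:
        raise UndefinedMetricError("empty ranking")
    step = max(1, math.ceil(step_fraction * n))
    sets = []
    cumulative: set[ResidueId] = set()
    for start in range(0, n, step):
        cumulative = cumulative | set(ranking[start:start + step])
        sets.append(set(cumulative))
    return curve_from_sets(sets, epitope, ranking)


def mean_auc(aucs: Sequence[float | None], undefined: str = "exclude") -> float:
    """Mean over per-target AUCs. ``undefined='exclude'`` drops targets with
    no defined AUC (warning); ``'zero'`` counts them as 0, the convention
    used when a predictor returns nothing for a target."""
    if undefined not in ("exclude", "zero"):
        raise ValueError("undefined must be 'exclude' or 'zero'")
    vals = []
    for a in aucs:
        if a is None:
            if undefined == "zero":
                vals.append(0.0)
            else:
                logger.warning("excluding target with undefined AUC from mean")
        else:
            vals.append(float(a))
    if not vals:
        raise UndefinedMetricError("no evaluable targets")
    return float(np.mean(vals))


def paired_auc_ttest(aucs_a: Sequence[float],
                     aucs_b: Sequence[float]) -> tuple[float, float]:
    """Paired t-test over per-target AUC vectors; returns (t, p)."""
    t, p = stats.ttest_rel(aucs_a, aucs_b)
    return float(t), float(p)
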