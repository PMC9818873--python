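"""ROC machinery: time-dependent ROC with KM correction and cutoff choice.

The time-dependent curve uses the cumulative-case / dynamic-control
estimator: cases are samples with an event by the horizon t, controls are
samples still event-free, and censoring before t is handled by
Kaplan-Meier estimates of survival within the score strata either side
of each candidate cutoff:

    Sens(c) = [1 - S(t | score > c)] P(score > c) / [1 - S(t)]
    Spec(c) = S(t | score <= c) P(score <= c) / S(t)

Candidate cutoffs are midpoints between consecutive sorted unique
scores; the grouping cutoff is the candidate closest to the (FPR 0,
TPR 1) corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .survival import _as_aligned_scores, _check_surv_arrays, km_estimate

__all__ = ["RocCurve", "time_dependent_roc", "select_cutoff", "binary_roc_auc"]


@dataclass
class RocCurve:
    """ROC evaluated over a cutoff grid (descending sensitivity order)."""

    cutoffs: np.ndarray       # candidate cutoffs (midpoints), ascending
    sensitivity: np.ndarray   # per cutoff
    specificity: np.ndarray   # per cutoff
    auc: float
    t_eval: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity


def _km_at(times: np.ndarray, events: np.ndarray, t: float) -> float:
    if times.size == 0:
        return 1.0
    return float(km_estimate(times, events)(t))


def time_dependent_roc(scores, surv: pd.DataFrame, t_eval: float = 60.0) -> RocCurve:
    """Time-dependent ROC of a risk score at horizon ``t_eval`` (months)."""
    s = _as_aligned_scores(scores, surv)
    times, events = _check_surv_arrays(surv["time_months"], surv["event"])
    if t_eval > times.max():
        raise ValueError(f"t_eval={t_eval} exceeds observed follow-up {times.max()}")
    if events[times <= t_eval].sum() == 0:
        raise ValueError(f"no events observed before t_eval={t_eval}")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical; ROC undefined")

    s_all = _km_at(times, events, t_eval)
    cutoffs = (uniq[:-1] + uniq[1:]) / 2.0
    n = s.size
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    for i, c in enumerate(cutoffs):
        hi = s > c
        p_hi = hi.mean()
        s_hi = _km_at(times[hi], events[hi], t_eval) if hi.any() else 1.0
        s_lo = _km_at(times[~hi], events[~hi], t_eval) if (~hi).any() else 1.0
        sens[i] = (1.0 - s_hi) * p_hi / (1.0 - s_all) if s_all < 1.0 else 0.0
        spec[i] = s_lo * (1.0 - p_hi) / s_all if s_all > 0.0 else 1.0
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # anchor at the corners and integrate in descending-cutoff order
    # (FPR ascends along that order; re-sorting would scramble vertical
    # runs that differ only by float noise)
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    roc_auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(cutoffs, sens, spec, roc_auc, t_eval,
                    metadata={"n": n, "estimator": "cumulative/dynamic KM"})


def select_cutoff(roc: RocCurve) -> float:
    """Cutoff minimizing the distance to the (FPR 0, TPR 1) corner.

    Ties break toward higher sensitivity, then toward the lower cutoff.
    """
    if roc.cutoffs.size == 0:
        raise ValueError("empty cutoff grid")
    d2 = (1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2
    best = d2.min()
    tied = np.flatnonzero(np.isclose(d2, best, rtol=0.0, atol=1e-12))
    best_sens = roc.sensitivity[tied].max()
    tied = tied[np.isclose(roc.sensitivity[tied], best_sens, rtol=0.0, atol=1e-12)]
    return float(roc.cutoffs[tied].min())


def binary_roc_auc(scores, labels) -> RocCurve:
    """Plain threshold-sweep ROC of scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    y = (labels == classes[1]).astype(int) if not np.array_equal(classes, [0, 1]) \
        else labels.astype(int)
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    roc_auc = float(_sk_auc(fpr, tpr))
    return RocCurve(cutoffs=thresholds[::-1], sensitivity=tpr[::-1],
                    specificity=1.0 - fpr[::-1], auc=roc_auc,
                    metadata={"n": scores.size, "estimator": "binary"})
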