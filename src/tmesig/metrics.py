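"""Cohort-level validation: aggregate per-model evaluation predictions into
one confusion matrix and derive accuracy, F1 and MCC.

Each sample typically lands in the evaluation half of about half the models;
its final prediction is the majority vote over those predictions, with ties
going to the negative class ("rest"). Samples never evaluated by any model
are excluded from the counts and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from tmesig.consensus import ModelRun
from tmesig.dichotomize import DichotomyLabels, HIGH

logger = logging.getLogger(__name__)

__all__ = ["ConfusionSummary", "aggregate_votes", "f1_score", "mcc_score", "accuracy_summary"]


@dataclass(frozen=True)
class ConfusionSummary:
    tn: int
    tp: int
    fn: int
    fp: int

    def __post_init__(self):
        for name in ("tn", "tp", "fn", "fp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_covered(self) -> int:
        return self.tn + self.tp + self.fn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_covered


def aggregate_votes(runs: list[ModelRun], labels: DichotomyLabels) -> ConfusionSummary:
    """Majority-vote per-sample predictions over all evaluation halves, then
    tally against the true labels. Vote ties predict "rest".
    """
    if not runs:
        raise ValueError("need at least one model run")
    votes_high: dict[str, int] = {}
    votes_total: dict[str, int] = {}
    for run in runs:
        for sample, pred in zip(run.eval_sample_ids, run.eval_predictions):
            votes_total[sample] = votes_total.get(sample, 0) + 1
            if pred == HIGH:
                votes_high[sample] = votes_high.get(sample, 0) + 1
    tn = tp = fn = fp = 0
    uncovered = []
    for sample in labels.sample_ids:
        total = votes_total.get(sample, 0)
        if total == 0:
            uncovered.append(sample)
            continue
        pred_high = votes_high.get(sample, 0) * 2 > total  # tie -> rest
        true_high = labels.is_high(sample)
        if pred_high and true_high:
            tp += 1
        elif pred_high:
            fp += 1
        elif true_high:
            fn += 1
        else:
            tn += 1
    if uncovered:
        logger.warning(
            "%d sample(s) never appeared in an evaluation half; excluded: %s%s",
            len(uncovered), ", ".join(uncovered[:5]), "..." if len(uncovered) > 5 else "",
        )
    return ConfusionSummary(tn=tn, tp=tp, fn=fn, fp=fp)


def f1_score(c: ConfusionSummary) -> float:
    """F1 = 2·tp / (2·tp + fp + fn); defined as 1 when tp = fp = fn = 0."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        logger.warning("F1 undefined (tp = fp = fn = 0); returning 1.0 by convention")
        return 1.0
    return 2 * c.tp / denom


def mcc_score(c: ConfusionSummary) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = c.tp * c.tn - c.fp * c.fn
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    return num / math.sqrt(math.prod(float(f) for f in factors))


def accuracy_summary(runs: list[ModelRun]) -> tuple[float, float, float, float]:
    """(mean, sd, min, max) of per-model evaluation accuracies (sd: n−1)."""
    if not runs:
        raise ValueError("need at least one model run")
    accs = np.array([r.eval_accuracy for r in runs], dtype=float)
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return float(accs.mean()), sd, float(accs.min()), float(accs.max())
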