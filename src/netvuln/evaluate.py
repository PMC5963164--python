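"""Candidate evaluation: single-marker ROC/AUC and prediction precision.

Each candidate microRNA is assessed as a stand-alone classifier of the two
sample groups using its expression values as the score. The AUC is computed
through the Mann-Whitney identity, AUC = U / (n_pos * n_neg), with tied
positive/negative score pairs contributing 1/2 — identical to the
probability that a random positive sample outscores a random negative one.
Down-regulated markers separate the groups with low scores, so each marker's
score is oriented by the sign of its discovery-set log2 fold change (negative
fold change flips the score) before the curve is built; the flip is recorded.

Prediction precision is the fraction of predicted candidates that appear in
a curated list of previously reported biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "roc_auc", "prediction_precision", "EmptyCandidateSetError"]


class EmptyCandidateSetError(ValueError):
    """Precision over an empty candidate set is undefined."""


@dataclass(frozen=True)
class ROCResult:
    """ROC curve and area for one marker.

    ``curve`` is the ordered list of (FPR, TPR) points from (0, 0) to (1, 1);
    ``oriented`` records whether the score sign was flipped before analysis.
    """

    mirna: str
    auc: float
    curve: tuple[tuple[float, float], ...]
    oriented: bool


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    orient_by: float | str = "none",
    mirna: str = "",
) -> ROCResult:
    """ROC analysis of one score vector against binary labels.

    Parameters
    ----------
    scores
        Per-sample marker values (e.g. log2 expression).
    labels
        Per-sample binary labels; 1 = positive class (the contrast group).
    orient_by
        ``"none"`` uses the scores as given; a real number orients by its
        sign — a negative value (a down-regulation fold change) negates the
        scores so that the marker's informative direction scores high.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    flipped = False
    if orient_by != "none":
        if float(orient_by) < 0:
            s = -s
            flipped = True
    # Mann-Whitney identity with midranks: ties count 1/2
    ranks = stats.rankdata(s)
    u = float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    curve = tuple(zip(map(float, fpr), map(float, tpr)))
    return ROCResult(mirna=mirna, auc=float(auc), curve=curve, oriented=flipped)


def prediction_precision(candidates: set[str], reported: set[str]) -> float:
    """Fraction of candidate microRNAs found in the reported-biomarker list."""
    if not candidates:
        raise EmptyCandidateSetError("precision of an empty candidate set is undefined")
    return len(candidates & reported) / len(candidates)
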