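"""Scoring predicted networks against ground truth; combining confidence matrices.

AUROC follows the Mann–Whitney convention (ties count one half); AUPR is
the area under the step-wise precision–recall curve over descending-score
thresholds, with tied scores entering as one threshold block — the
DREAM-challenge style of evaluation.  Self-regulation is excluded by
default, since diagonal scores are not comparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .state import ConfidenceMatrix


@dataclass
class ScoredPrediction:
    """Ordered candidate edges with confidences, plus the binary truth."""

    scores: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.truth = np.asarray(self.truth, dtype=int).ravel()
        if self.scores.shape != self.truth.shape:
            raise ValueError("scores and truth must have equal length")
        if not np.all((self.truth == 0) | (self.truth == 1)):
            raise ValueError("truth must be binary")


def prediction_from_matrices(
    cm: ConfidenceMatrix | np.ndarray,
    truth: np.ndarray,
    exclude_self: bool = True,
) -> ScoredPrediction:
    """Flatten a confidence matrix and truth adjacency into scored edges.

    Only the n x n gene block is scored (external-input columns are
    dropped); the diagonal is removed when ``exclude_self``.
    """
    probs = np.asarray(getattr(cm, "probs", cm), dtype=float)
    truth = np.asarray(truth, dtype=int)
    n = truth.shape[0]
    probs = probs[:, :n]
    if exclude_self:
        mask = ~np.eye(n, dtype=bool)
        return ScoredPrediction(scores=probs[mask], truth=truth[mask])
    return ScoredPrediction(scores=probs.ravel(), truth=truth.ravel())


def auroc(pred: ScoredPrediction) -> float:
    """Probability that a random true edge outscores a random false edge.

    Computed from midranks, so tied scores contribute one half.
    """
    pos = pred.truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined without both true and false edges")
    ranks = rankdata(pred.scores)
    u = np.sum(ranks[pos]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(pred: ScoredPrediction) -> float:
    """Area under the step-wise precision–recall curve.

    Thresholds descend through the distinct score values; each tied block
    enters at once.  The area is sum over blocks of
    (recall gain) x (precision at the block), so a perfect ranking scores 1
    regardless of class sizes.
    """
    n_pos = int(np.sum(pred.truth))
    if n_pos == 0:
        raise ValueError("AUPR undefined without at least one true edge")
    order = np.argsort(-pred.scores, kind="stable")
    scores = pred.scores[order]
    truth = pred.truth[order]
    # block boundaries where the score strictly drops
    boundaries = np.flatnonzero(np.diff(scores) != 0)
    block_ends = np.concatenate([boundaries, [scores.size - 1]])
    tp = np.cumsum(truth)[block_ends]
    k = block_ends + 1.0
    precision = tp / k
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def combine_scores(cm_a, cm_b) -> ConfidenceMatrix:
    """Element-wise product of two confidence matrices.

    Favors links that score high in both methods — the standard way of
    combining a time-series-based prediction with an independent
    steady-state one.
    """
    a = np.asarray(getattr(cm_a, "probs", cm_a), dtype=float)
    b = np.asarray(getattr(cm_b, "probs", cm_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = getattr(cm_a, "n_samples", 1)
    nb = getattr(cm_b, "n_samples", 1)
    return ConfidenceMatrix(
        probs=a * b,
        n_samples=min(int(na), int(nb)),
        gene_names=getattr(cm_a, "gene_names", None),
        input_names=getattr(cm_a, "input_names", None),
    )


def probability_histogram(cm, bins: int | np.ndarray = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of off-diagonal posterior link probabilities.

    Useful for picking a reporting threshold: a gap in the histogram
    separates confident links from background.  Returns (counts, bin_edges).
    """
    probs = np.asarray(getattr(cm, "probs", cm), dtype=float)
    n = probs.shape[0]
    vals = probs[:, :n][~np.eye(n, dtype=bool)]
    extra = probs[:, n:].ravel()  # input columns have no diagonal to drop
    vals = np.concatenate([vals, extra])
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return counts, edges
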