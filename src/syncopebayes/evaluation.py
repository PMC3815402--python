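"""Discrimination metrics: ROC curve, c-statistic, fixed-cutoff
sensitivity/specificity, and the Mann-Whitney rank-sum test.

The c-statistic is the probability that a randomly chosen cardiac
patient receives a higher predicted probability than a randomly chosen
non-cardiac patient, ties counted one half — identical to the area
under the empirical ROC curve and related to the Mann-Whitney statistic
by U = c * n1 * n0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateTableError
from .predictors import CARDIAC


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == CARDIAC if labels.dtype.kind in "OUS" else labels.astype(bool)
    x = scores[pos]
    y = scores[~pos]
    if len(x) == 0 or len(y) == 0:
        raise DegenerateTableError("both diagnosis classes must be present")
    return x, y


def c_statistic(scores, labels) -> float:
    """Tie-corrected pairwise concordance probability.

    Computed from midranks: with R1 the rank sum of the cardiac scores,
    U = R1 - n1(n1+1)/2 and c = U / (n1 n0); midranks give ties a
    weight of one half, so this equals explicit pair counting.
    """
    x, y = _split(scores, labels)
    n1, n0 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with thresholds at the unique observed scores
    (descending, +inf sentinel first) and the tie-corrected c-statistic."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    c_statistic: float

    def trapezoidal_area(self) -> float:
        return float(np.trapezoid(self.sensitivity, self.one_minus_specificity))


def roc_curve(scores, labels) -> ROCResult:
    """ROC points for predicted probabilities against true diagnoses.

    The curve starts at (0,0) and ends at (1,1); both coordinates are
    non-decreasing as the threshold falls.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _split(scores, labels)  # class-presence check
    pos = labels == CARDIAC if labels.dtype.kind in "OUS" else labels.astype(bool)
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores, drop_intermediate=False)
    return ROCResult(thr, tpr, fpr, c_statistic(scores, labels))


def sens_spec_at(scores, labels, cutoff: float = 0.02) -> tuple[float, float]:
    """Sensitivity and specificity at a fixed probability cutoff.

    A score exactly at the cutoff counts as a cardiac call (the
    sensitivity-favouring boundary convention).
    """
    x, y = _split(scores, labels)
    sens = float(np.mean(x >= cutoff))
    spec = float(np.mean(y < cutoff))
    return sens, spec


def rank_sum_test(scores_cardiac, scores_noncardiac) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (normal approximation with tie
    correction) that cardiac posteriors exceed non-cardiac posteriors.
    Returns (U, p) where U is the statistic of the cardiac group, so
    U = c_statistic * n1 * n0."""
    x = np.asarray(scores_cardiac, dtype=float)
    y = np.asarray(scores_noncardiac, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateTableError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)
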