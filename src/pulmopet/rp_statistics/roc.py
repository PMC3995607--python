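"""ROC analysis: trapezoidal AUC, DeLong variance, Youden operating point.

The AUC is the Mann-Whitney pairwise-concordance probability; its variance is
estimated nonparametrically from DeLong's structural components (the per-case
placement values), giving a Wald 95% CI.  The Youden point maximises
``J = sensitivity + specificity - 1`` over the observed thresholds, breaking
ties toward higher specificity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from ._common import Z95


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci_95: tuple[float, float]
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    ci_defined: bool = True

    @property
    def youden_j(self) -> float:
        return self.youden_sensitivity + self.youden_specificity - 1.0


def auc_mann_whitney(scores, outcomes) -> float:
    """AUC as the normalised Mann-Whitney U statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    pos, neg = scores[y], scores[~y]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    r = rankdata(np.concatenate([pos, neg]))
    return float((r[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_se(scores, y) -> float:
    """DeLong structural-component standard error of the AUC."""
    pos, neg = scores[y], scores[~y]
    m, n = pos.size, neg.size
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n            # placements of positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m      # placements of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_delong_youden(scores, outcomes) -> RocResult:
    """Full ROC result for a score against a binary outcome.

    Constant scores yield AUC 0.5 with a warning; the CI is then flagged as
    undefined rather than fabricated.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: AUC is 0.5 and its CI is undefined", stacklevel=2)
        return RocResult(np.array([scores[0]]), np.array([1.0]), np.array([0.0]),
                         auc=0.5, auc_se=float("nan"),
                         auc_ci_95=(float("nan"), float("nan")),
                         youden_threshold=float(scores[0]),
                         youden_sensitivity=1.0, youden_specificity=0.0,
                         ci_defined=False)
    fpr, tpr, thresholds = roc_curve(y.astype(int), scores, drop_intermediate=False)
    sens, spec = tpr, 1.0 - fpr
    j = sens + spec - 1.0
    best = int(np.argmax(j))             # roc_curve orders by increasing fpr, so the
    auc = auc_mann_whitney(scores, y)    # first maximum has the highest specificity
    se = _delong_se(scores, y)
    ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, auc_se=se, auc_ci_95=ci,
                     youden_threshold=float(thresholds[best]),
                     youden_sensitivity=float(sens[best]),
                     youden_specificity=float(spec[best]))
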