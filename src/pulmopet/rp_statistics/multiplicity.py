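"""Holm's sequentially rejective Bonferroni adjustment."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._common import ALPHA


@dataclass(frozen=True)
class HolmResult:
    raw: np.ndarray
    adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def holm_adjust(p_values, alpha: float = ALPHA) -> HolmResult:
    """Holm step-down adjustment of a family of p-values.

    Sorted ascending, ``p_(i)`` is compared against ``alpha / (m - i + 1)``;
    rejection stops at the first failure.  Adjusted p-values are monotone
    non-decreasing and never smaller than the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D collection")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return HolmResult(raw=p, adjusted=adjusted, rejected=rejected, alpha=alpha)
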