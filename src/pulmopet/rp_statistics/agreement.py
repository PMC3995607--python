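"""Inter-reader agreement: Bland-Altman limits from one-way ANOVA.

Each reading is expressed as its percent deviation from the subject mean;
the 95% limits of agreement are ``mean deviation +/- 1.96 * sqrt(MS_within)``
where ``MS_within`` is the within-subject mean square of a one-way ANOVA with
subject as the random factor (degrees of freedom ``N - k`` for ``N`` readings
on ``k`` subjects).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._common import Z95


@dataclass(frozen=True)
class AgreementResult:
    deviations_pct: pd.DataFrame        # subjects x readers, percent deviation
    mean_deviation_pct: float
    within_subject_sd_pct: float        # sqrt(MS_within)
    limits_of_agreement_pct: tuple[float, float]
    n_subjects: int
    n_readings: int

    @property
    def loa_halfwidth_pct(self) -> float:
        lo, hi = self.limits_of_agreement_pct
        return (hi - lo) / 2.0


def bland_altman_loa(readings: pd.DataFrame | np.ndarray) -> AgreementResult:
    """Limits of agreement for a subjects-by-readers reading matrix.

    Subjects with fewer than two readings are excluded with a warning; all
    readings must be strictly positive (deviations are relative).
    """
    mat = pd.DataFrame(readings).astype(float)
    if mat.shape[1] < 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 readers and >= 2 subjects")
    counts = mat.notna().sum(axis=1)
    if (counts < 2).any():
        dropped = list(mat.index[counts < 2])
        warnings.warn(f"excluding subject(s) with a single reading: {dropped}",
                      stacklevel=2)
        mat = mat[counts >= 2]
    if mat.shape[0] < 2:
        raise ValueError("fewer than 2 subjects remain after exclusions")
    if (mat <= 0).any().any():
        raise ValueError("all readings must be > 0")

    subject_mean = mat.mean(axis=1)
    dev = 100.0 * mat.sub(subject_mean, axis=0).div(subject_mean, axis=0)
    n_readings = int(mat.notna().sum().sum())
    k = mat.shape[0]
    # per-subject deviation means are exactly 0 by construction
    ss_within = float((dev ** 2).sum().sum())
    ms_within = ss_within / (n_readings - k)
    sd = float(np.sqrt(ms_within))
    mean_dev = float(dev.stack().mean())
    return AgreementResult(
        deviations_pct=dev, mean_deviation_pct=mean_dev, within_subject_sd_pct=sd,
        limits_of_agreement_pct=(mean_dev - Z95 * sd, mean_dev + Z95 * sd),
        n_subjects=k, n_readings=n_readings)
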