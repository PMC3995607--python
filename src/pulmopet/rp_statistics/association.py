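"""Marginal association tests between covariates and symptomatic status.

Categorical covariates use Pearson's chi-squared test on the contingency
table (with Yates continuity correction for 2x2 tables, uncorrected for
larger ones); continuous covariates use the two-sided Mann-Whitney U test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import expected_freq


@dataclass(frozen=True)
class AssociationResult:
    covariate: str
    test: str                     # "chi2" or "mann_whitney"
    statistic: float
    p_value: float
    df: int | None = None
    n: int = 0


def association_tests(records: pd.DataFrame, covariate: str,
                      outcome: str = "symptomatic",
                      kind: str | None = None) -> AssociationResult:
    """Test the association of one covariate with the binary outcome.

    ``kind`` is ``"categorical"`` or ``"continuous"``; when omitted it is
    inferred from the column dtype.
    """
    data = records[[covariate, outcome]].dropna()
    x = data[covariate]
    y = data[outcome].astype(int)
    if kind is None:
        kind = "continuous" if pd.api.types.is_numeric_dtype(x) and x.nunique() > 5 \
            else "categorical"

    if kind == "categorical":
        table = pd.crosstab(x, y, dropna=False)   # keep declared-but-unseen levels visible
        expected = expected_freq(table.to_numpy())
        if (expected == 0).any():
            raise ValueError(
                f"contingency table for {covariate!r} has an expected cell count of 0; "
                "merge sparse categories before testing")
        correction = table.shape == (2, 2)
        res = stats.chi2_contingency(table.to_numpy(), correction=correction)
        return AssociationResult(covariate, "chi2", float(res.statistic),
                                 float(res.pvalue), int(res.dof), len(data))
    if kind == "continuous":
        g1 = x[y == 1].to_numpy()
        g0 = x[y == 0].to_numpy()
        if len(g1) == 0 or len(g0) == 0:
            raise ValueError("both outcome groups must be non-empty for Mann-Whitney")
        u = stats.mannwhitneyu(g1, g0, alternative="two-sided")
        return AssociationResult(covariate, "mann_whitney", float(u.statistic),
                                 float(min(u.pvalue, 1.0)), None, len(data))
    raise ValueError(f"kind must be 'categorical' or 'continuous', got {kind!r}")
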