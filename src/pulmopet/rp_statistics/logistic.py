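"""Logistic regression for grade >= 2 radiation pneumonitis.

Maximum-likelihood fits (Newton/IRLS via statsmodels), two-sided Wald tests,
odds ratios with 95% Wald intervals, and Nagelkerke's rescaled R².
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._common import Z95, ModelFitError

_MAX_ABS_COEF = 20.0  # beyond this a binary-covariate logit is effectively separated


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic model; odds ratios are exp(coef) with Wald 95% CIs."""

    terms: tuple[str, ...]
    outcome: str
    coef: pd.Series
    se: pd.Series
    n: int
    llf: float
    llnull: float
    aic: float
    nagelkerke_r2: float
    _model: object = field(repr=False, default=None)

    @property
    def z(self) -> pd.Series:
        return self.coef / self.se

    @property
    def p_values(self) -> pd.Series:
        from scipy import stats
        return pd.Series(2 * stats.norm.sf(np.abs(self.z)), index=self.coef.index)

    @property
    def odds_ratios(self) -> pd.DataFrame:
        """OR = exp(coef); CI = exp(coef +/- 1.96 SE). Intercept excluded."""
        idx = [t for t in self.coef.index if t != "intercept"]
        return pd.DataFrame({
            "or": np.exp(self.coef[idx]),
            "ci_low": np.exp(self.coef[idx] - Z95 * self.se[idx]),
            "ci_high": np.exp(self.coef[idx] + Z95 * self.se[idx]),
        })

    def summary_frame(self) -> pd.DataFrame:
        """Publication-style table: coefficient, SE, OR (95% CI), p-value."""
        out = pd.DataFrame({"coefficient": self.coef, "se": self.se,
                            "p_value": self.p_values})
        ors = self.odds_ratios
        out["odds_ratio"] = ors["or"]
        out["or_ci_low"] = ors["ci_low"]
        out["or_ci_high"] = ors["ci_high"]
        return out

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Predicted event probabilities."""
        X = sm.add_constant(records[list(self.terms)].astype(float), has_constant="add")
        lp = X.to_numpy() @ np.r_[self.coef["intercept"],
                                  self.coef[list(self.terms)].to_numpy()]
        return 1.0 / (1.0 + np.exp(-lp))


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke's coefficient of determination.

    ``R² = [1 − exp((2/n)(LL₀ − LL₁))] / [1 − exp((2/n) LL₀)]`` — the
    Cox-Snell R² rescaled by its maximum attainable value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if llf < llnull - 1e-8:
        raise ValueError("fitted log-likelihood below the null log-likelihood; "
                         "the models are not nested MLE fits on the same records")
    cox_snell = 1.0 - np.exp((2.0 / n) * (llnull - llf))
    max_cs = 1.0 - np.exp((2.0 / n) * llnull)
    if max_cs <= 0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


def fit_logistic(records: pd.DataFrame, terms: list[str],
                 outcome: str = "symptomatic") -> LogisticFit:
    """Fit ``outcome ~ intercept + terms`` by maximum likelihood.

    Complete-case analysis; complete separation or non-convergence raises
    :class:`ModelFitError` naming the offending term.
    """
    cols = list(terms) + [outcome]
    data = records[cols].dropna()
    if len(data) < 10:
        raise ValueError(f"need >= 10 complete records, got {len(data)}")
    y = data[outcome].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome is constant; nothing to model")
    X = sm.add_constant(data[list(terms)].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*Maximum Likelihood optimization.*")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        except Exception as exc:  # statsmodels raises several flavours here
            raise ModelFitError(f"logistic fit failed for terms {list(terms)}: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    bad = [t for t, c, s in zip(X.columns, params, bse)
           if (t != "const" and abs(c) > _MAX_ABS_COEF) or not np.isfinite(s)]
    if bad:
        raise ModelFitError(
            f"complete separation or non-convergence in logistic fit; offending term(s): {bad}")
    index = ["intercept"] + list(terms)
    coef = pd.Series(params, index=index)
    se = pd.Series(bse, index=index)
    k = len(terms) + 1
    llf = float(res.llf)
    llnull = float(res.llnull)
    return LogisticFit(
        terms=tuple(terms), outcome=outcome, coef=coef, se=se, n=len(data),
        llf=llf, llnull=llnull, aic=float(-2 * llf + 2 * k),
        nagelkerke_r2=nagelkerke_r2(llf, llnull, len(data)), _model=res)
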