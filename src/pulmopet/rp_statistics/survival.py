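"""Time-to-symptom analyses: Kaplan-Meier terciles and Cox regression.

Kaplan-Meier curves compare symptom onset across SUV95 terciles (boundaries
computed empirically, or pinned at 0.99/1.2 in paper-compat mode).  Cox
proportional-hazards fits use lifelines with Efron tie handling; hazard
ratios are exp(coef) with Wald 95% intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from ._common import Z95, ModelFitError

#: SUV95 tercile boundaries observed in the original patient study, used by
#: the paper-compat stratification mode.
PAPER_COMPAT_TERCILES = (0.99, 1.2)

_MAX_ABS_COEF = 20.0


def tercile_boundaries(values, paper_compat: bool = False) -> tuple[float, float]:
    """Lower/upper tercile boundaries of a biomarker distribution."""
    if paper_compat:
        return PAPER_COMPAT_TERCILES
    v = np.asarray(values, dtype=float)
    return (float(np.percentile(v, 100 / 3)), float(np.percentile(v, 200 / 3)))


@dataclass
class KMStratum:
    label: str
    n: int
    n_events: int
    timeline: np.ndarray
    survival: np.ndarray            # non-increasing, starts at 1
    censor_times: np.ndarray
    median: float | None            # earliest time with survival <= 0.5; None if never


@dataclass
class KMResult:
    strata: list[KMStratum]
    boundaries: tuple[float, float]
    tercile_hazard_ratios: pd.DataFrame | None = None

    def stratum(self, label: str) -> KMStratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class CoxFit:
    """Cox PH fit; hazard ratios are exp(coef) with Wald 95% CIs."""

    terms: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    n: int
    n_events: int
    log_likelihood: float
    aic_partial: float
    zero_variance_terms: tuple[str, ...] = ()

    @property
    def p_values(self) -> pd.Series:
        from scipy import stats
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.coef.index)
        p[list(self.zero_variance_terms)] = 1.0
        return p

    @property
    def hazard_ratios(self) -> pd.DataFrame:
        hr = np.exp(self.coef)
        with np.errstate(invalid="ignore"):
            lo = np.exp(self.coef - Z95 * self.se)
            hi = np.exp(self.coef + Z95 * self.se)
        out = pd.DataFrame({"hr": hr, "ci_low": lo, "ci_high": hi})
        for t in self.zero_variance_terms:
            out.loc[t] = [1.0, np.nan, np.nan]
        return out

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"coefficient": self.coef, "se": self.se,
                            "p_value": self.p_values})
        hrs = self.hazard_ratios
        out["hazard_ratio"] = hrs["hr"]
        out["hr_ci_low"] = hrs["ci_low"]
        out["hr_ci_high"] = hrs["ci_high"]
        return out


def km_fit(records: pd.DataFrame, value_col: str = "suv_95",
           boundaries: tuple[float, float] | None = None,
           duration_col: str = "time_days", event_col: str = "event",
           paper_compat: bool = False) -> KMResult:
    """Product-limit curves per biomarker tercile, with pairwise hazard ratios.

    The stratum median is the earliest time at which the survival estimate
    drops to <= 0.5, reported as ``None`` when never reached.
    """
    data = records[[value_col, duration_col, event_col]].dropna()
    if (data[duration_col] <= 0).any():
        raise ValueError("all times must be > 0")
    if boundaries is None:
        boundaries = tercile_boundaries(data[value_col], paper_compat=paper_compat)
    lo, hi = boundaries
    labels = [f"{value_col} < {lo:.3g}", f"{lo:.3g} <= {value_col} < {hi:.3g}",
              f"{value_col} >= {hi:.3g}"]
    codes = np.digitize(data[value_col].to_numpy(), [lo, hi])

    strata: list[KMStratum] = []
    for code, label in enumerate(labels):
        sub = data[codes == code]
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        med = kmf.median_survival_time_
        strata.append(KMStratum(
            label=label, n=len(sub), n_events=int(sub[event_col].sum()),
            timeline=kmf.survival_function_.index.to_numpy(),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            censor_times=sub.loc[sub[event_col] == 0, duration_col].to_numpy(),
            median=None if np.isinf(med) else float(med)))

    hr_table = None
    if len(strata) > 1 and data[event_col].sum() > 0:
        dummies = pd.DataFrame({
            "tercile_2": (codes == 1).astype(float),
            "tercile_3": (codes == 2).astype(float),
            duration_col: data[duration_col].to_numpy(),
            event_col: data[event_col].to_numpy()})
        try:
            fit = cox_fit(dummies, ["tercile_2", "tercile_3"],
                          duration_col=duration_col, event_col=event_col,
                          min_events=1)
            hr_table = fit.summary_frame()
        except (ModelFitError, ValueError):
            hr_table = None
    return KMResult(strata=strata, boundaries=boundaries, tercile_hazard_ratios=hr_table)


def cox_fit(records: pd.DataFrame, terms: list[str],
            duration_col: str = "time_days", event_col: str = "event",
            min_events: int = 10) -> CoxFit:
    """Cox proportional-hazards fit by partial likelihood (Efron ties).

    Zero-variance covariates are pinned to coefficient 0 / HR 1 rather than
    passed to the optimiser; monotone partial likelihood (e.g. a level with
    no events) raises :class:`ModelFitError`.
    """
    cols = list(terms) + [duration_col, event_col]
    data = records[cols].dropna()
    n_events = int(data[event_col].sum())
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} events, got {n_events}")
    if (data[duration_col] <= 0).any():
        raise ValueError("all times must be > 0")

    zero_var = tuple(t for t in terms if data[t].nunique() <= 1)
    active = [t for t in terms if t not in zero_var]
    index = list(terms)
    coef = pd.Series(0.0, index=index)
    se = pd.Series(np.inf, index=index)
    ll = float("nan")
    if active:
        cph = CoxPHFitter()
        try:
            cph.fit(data[active + [duration_col, event_col]],
                    duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            raise ModelFitError(f"Cox fit failed (monotone likelihood or separation) "
                                f"for terms {active}: {exc}") from exc
        bad = [t for t in active if abs(cph.params_[t]) > _MAX_ABS_COEF]
        if bad:
            raise ModelFitError(f"Cox coefficients diverged (monotone likelihood); "
                                f"offending term(s): {bad}")
        coef[active] = cph.params_[active]
        se[active] = cph.standard_errors_[active]
        ll = float(cph.log_likelihood_)
    else:
        ll = _cox_null_loglik(data[duration_col].to_numpy(),
                              data[event_col].to_numpy().astype(bool))
    aic = -2.0 * ll + 2.0 * len(active)
    return CoxFit(terms=tuple(terms), coef=coef, se=se, n=len(data),
                  n_events=n_events, log_likelihood=ll, aic_partial=aic,
                  zero_variance_terms=zero_var)


def _cox_null_loglik(durations: np.ndarray, events: np.ndarray) -> float:
    """Partial log-likelihood of the empty Cox model under Efron tie handling."""
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    e = events[order]
    n = len(t)
    ll = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        at_risk = n - i
        for k in range(d):
            ll -= np.log(at_risk - k)
        i = j
    return float(ll)
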