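"""Stepwise backward model selection on the Akaike information criterion.

Starting from the full model, the single term whose removal most lowers the
AIC is dropped, repeatedly, until no removal lowers it.  Works for logistic
models (ordinary AIC) and Cox models (generalised AIC on the partial
likelihood).  Deterministic given the data: strict improvement is required
and ties resolve to the earliest candidate in the supplied order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .logistic import LogisticFit, fit_logistic
from .survival import CoxFit, cox_fit, _cox_null_loglik


@dataclass(frozen=True)
class SelectionStep:
    dropped: str
    aic_before: float
    aic_after: float


@dataclass
class SelectionResult:
    selected_terms: tuple[str, ...]
    fit: "LogisticFit | CoxFit | None"   # None only for an empty Cox model
    aic: float
    history: list[SelectionStep] = field(default_factory=list)


def _aic(records: pd.DataFrame, terms: list[str], family: str,
         outcome: str, duration_col: str, event_col: str, penalty: float):
    if family == "logistic":
        if terms:
            fit = fit_logistic(records, terms, outcome=outcome)
            return -2.0 * fit.llf + penalty * (len(terms) + 1), fit
        # intercept-only model, closed form
        import numpy as np
        y = records[outcome].dropna().astype(int).to_numpy()
        p = y.mean()
        ll0 = float(y.sum() * np.log(p) + (len(y) - y.sum()) * np.log(1 - p)) \
            if 0 < p < 1 else 0.0
        return -2.0 * ll0 + penalty * 1, None
    if family == "cox":
        if terms:
            fit = cox_fit(records, terms, duration_col=duration_col, event_col=event_col)
            return -2.0 * fit.log_likelihood + penalty * len(terms), fit
        data = records[[duration_col, event_col]].dropna()
        ll0 = _cox_null_loglik(data[duration_col].to_numpy(),
                               data[event_col].to_numpy().astype(bool))
        return -2.0 * ll0, None
    raise ValueError(f"model_family must be 'logistic' or 'cox', got {family!r}")


def backward_aic_select(records: pd.DataFrame, candidate_terms: list[str],
                        model_family: str = "logistic",
                        outcome: str = "symptomatic",
                        duration_col: str = "time_days", event_col: str = "event",
                        penalty: float = 2.0) -> SelectionResult:
    """Backward-eliminate candidates until no drop lowers the (generalised) AIC.

    The records must be complete for every candidate (complete-case over the
    full candidate set, so all AICs are comparable).  A failing full-model fit
    propagates as an error.
    """
    if not candidate_terms:
        raise ValueError("candidate set must be non-empty")
    cols = list(candidate_terms) + ([outcome] if model_family == "logistic"
                                    else [duration_col, event_col])
    data = records[cols].dropna()
    current = list(candidate_terms)
    aic_cur, fit_cur = _aic(data, current, model_family, outcome,
                            duration_col, event_col, penalty)
    history: list[SelectionStep] = []
    while current:
        best = None
        for term in current:
            reduced = [t for t in current if t != term]
            aic_try, fit_try = _aic(data, reduced, model_family, outcome,
                                    duration_col, event_col, penalty)
            if aic_try < aic_cur - 1e-9 and (best is None or aic_try < best[0] - 1e-9):
                best = (aic_try, term, fit_try)
        if best is None:
            break
        aic_new, dropped, fit_cur = best
        history.append(SelectionStep(dropped, aic_cur, aic_new))
        aic_cur = aic_new
        current = [t for t in current if t != dropped]
    return SelectionResult(selected_terms=tuple(current), fit=fit_cur,
                           aic=aic_cur, history=history)
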