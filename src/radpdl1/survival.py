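"""Prognostic analysis of the rad-PDL1 score.

The continuous score is dichotomized into High/Low groups with a cutoff
chosen on the training cohort only (a log-rank-maximizing scan over score
quantiles with a minimum-group-size constraint, emulating the X-tile
procedure) and then frozen.  Group prognosis is quantified by Kaplan-Meier
curves, the log-rank test, and multivariate Cox proportional-hazards
regression with Efron tie handling, including a Schoenfeld-residual check
of the proportional-hazards assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test


def select_cutoff(train_scores, train_times, train_events,
                  min_group_fraction: float = 0.1,
                  n_candidates: int = 50) -> float:
    """Training-only score cutoff maximizing the log-rank statistic.

    Candidates are the observed score quantiles; cutoffs leaving either
    group below ``min_group_fraction`` of patients are inadmissible.  The
    chosen value is frozen and applied unchanged to any test set.
    """
    s = np.asarray(train_scores, dtype=np.float64)
    t = np.asarray(train_times, dtype=np.float64)
    e = np.asarray(train_events).astype(int)
    if s.size < 20 or e.sum() < 5:
        raise ValueError("cutoff selection needs >= 20 patients with >= 5 "
                         "events")
    qs = np.linspace(min_group_fraction, 1.0 - min_group_fraction,
                     n_candidates)
    candidates = np.unique(np.quantile(s, qs))
    best_stat, best_cut = -np.inf, None
    n = s.size
    for cut in candidates:
        hi = s >= cut
        frac = hi.mean()
        if frac < min_group_fraction or frac > 1.0 - min_group_fraction:
            continue
        if e[hi].sum() == 0 or e[~hi].sum() == 0:
            continue
        stat = _ll_logrank(t[hi], t[~hi], e[hi], e[~hi]).test_statistic
        if stat > best_stat:
            best_stat, best_cut = stat, float(cut)
    if best_cut is None:
        raise ValueError("no admissible cutoff under the group-size "
                         "constraint")
    return best_cut


@dataclass
class KMResult:
    times: np.ndarray            # event/censor times (sorted, unique)
    survival: np.ndarray         # S(t) at those times
    median: float | None         # first t with S(t) <= 0.5; None if never
    censor_times: np.ndarray     # times of censored observations


def km_estimate(times, events) -> KMResult:
    """Product-limit survival estimate with the first-crossing median."""
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events).astype(int)
    if t.size < 1:
        raise ValueError("need at least one observation")
    km = KaplanMeierFitter()
    km.fit(t, e)
    sf = km.survival_function_
    med = km.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMResult(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy(), median,
                    np.sort(t[e == 0]))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank statistic and two-sided p-value."""
    ea = np.asarray(events_a).astype(int)
    eb = np.asarray(events_b).astype(int)
    if ea.sum() == 0 and eb.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(np.asarray(times_a, dtype=float),
                      np.asarray(times_b, dtype=float), ea, eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    summary: pd.DataFrame        # coef, HR, CI bounds, p per covariate
    converged: bool
    ties_method: str
    ph_test: pd.DataFrame | None  # Schoenfeld-residual trend test


def cox_ph(df: pd.DataFrame, duration_col: str = "time_months",
           event_col: str = "event",
           covariates: list[str] | None = None) -> CoxFit:
    """Multivariate Cox PH fit (Efron ties) with Wald CIs and a
    proportional-hazards diagnostic per covariate.

    Warns when events < 5x the covariate count; collinear or separated
    designs surface as a ConvergenceError with an actionable message.
    """
    if covariates is None:
        covariates = [c for c in df.columns
                      if c not in (duration_col, event_col)]
    data = df[[duration_col, event_col] + covariates].copy()
    n_events = int(data[event_col].sum())
    if n_events < 5 * len(covariates):
        import warnings
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates; "
            "estimates may be unstable", stacklevel=2)
    # collinearity guard: exactly duplicated columns break the fit silently
    Xc = data[covariates].to_numpy(dtype=np.float64)
    corr = np.corrcoef(Xc, rowvar=False)
    if len(covariates) > 1:
        iu = np.triu_indices(len(covariates), k=1)
        worst = np.nanmax(np.abs(corr[iu]))
        if worst > 0.999:
            raise ValueError(
                "covariate matrix is collinear (|r| > 0.999 between two "
                "columns); drop the duplicated covariate")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ValueError(
            "Cox model failed to converge - check for separation or "
            f"near-collinearity: {err}"
        ) from err
    summ = cph.summary[["coef", "exp(coef)", "exp(coef) lower 95%",
                        "exp(coef) upper 95%", "p"]].copy()
    summ.columns = ["coef", "hr", "hr_lo", "hr_hi", "p"]
    try:
        ph = proportional_hazard_test(cph, data).summary
    except Exception:   # diagnostic only; never blocks the fit
        ph = None
    return CoxFit(summ, True, "efron", ph)
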