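"""Survival analysis: Kaplan-Meier curves, log-rank tests and Cox models.

Thin, validated wrappers around lifelines.  The Cox fit uses the partial
likelihood with Efron tie handling (lifelines' default); categorical
covariates are reference-coded against their largest category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = ["KMCurve", "km_estimate", "logrank_test", "cox_fit"]


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None  # first time S(t) <= 0.5; None if never reached
    n: int
    n_events: int


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t <= 0).any() or not np.isfinite(t).all():
        raise ValueError("survival times must be positive and finite")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be coded 0/1")
    return t, e.astype(int)


def km_estimate(times, events, groups=None) -> dict:
    """Product-limit survival estimate, per group when ``groups`` is given.

    The median is the first event time at which S(t) falls to 0.5 or below,
    and None when the curve never crosses 0.5 (small or lightly censored
    groups).
    """
    t, e = _validate(times, events)
    g = np.asarray(groups) if groups is not None else np.zeros(t.size, dtype=int)
    out = {}
    for level in pd.unique(g):
        sel = g == level
        if sel.sum() == 0:
            raise ValueError(f"empty group {level!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        med = kmf.median_survival_time_
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy()
        out[level] = KMCurve(
            times=surv.index.to_numpy(dtype=float),
            survival=surv.to_numpy(dtype=float),
            at_risk=at_risk,
            median=None if np.isinf(med) else float(med),
            n=int(sel.sum()),
            n_events=int(e[sel].sum()),
        )
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Multi-group log-rank test.

    Observed-minus-expected statistic with hypergeometric variance; p-value
    from the chi-square distribution with (groups - 1) degrees of freedom.
    """
    t, e = _validate(times, events)
    g = np.asarray(groups)
    if len(pd.unique(g)) < 2:
        raise ValueError("log-rank test requires >= 2 groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def _design_matrix(df: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = []
    for cov in covariates:
        s = df[cov]
        if s.nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            ref = s.value_counts().idxmax()
            dummies = pd.get_dummies(s, prefix=cov, dtype=float)
            dummies = dummies.drop(columns=f"{cov}_{ref}")
            cols.append(dummies)
        else:
            cols.append(s.astype(float).to_frame(cov))
    return pd.concat(cols, axis=1)


def cox_fit(
    table: pd.DataFrame,
    covariates,
    mode: str = "multivariable",
    duration_col: str = "os_time",
    event_col: str = "os_event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate level.

    ``mode='univariable'`` fits each covariate separately; 'multivariable'
    fits them jointly.  Returns hazard ratios with Wald 95% CIs and p-values
    plus the model log-likelihood.  Categorical covariates are
    reference-coded against the largest category.
    """
    if mode not in ("univariable", "multivariable"):
        raise ValueError("mode must be 'univariable' or 'multivariable'")
    _validate(table[duration_col], table[event_col])
    groups = [[c] for c in covariates] if mode == "univariable" else [list(covariates)]
    rows = []
    for covs in groups:
        X = _design_matrix(table, covs)
        df = pd.concat(
            [table[[duration_col, event_col]].reset_index(drop=True),
             X.reset_index(drop=True)], axis=1)
        if df[event_col].sum() < X.shape[1] + 1:
            raise ValueError("too few events for the number of parameters")
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as err:
            raise ValueError(f"Cox fit failed to converge for {covs}: {err}") from err
        summ = cph.summary
        for name in X.columns:
            rows.append({
                "covariate": name,
                "mode": mode,
                "hr": float(summ.loc[name, "exp(coef)"]),
                "ci_low": float(summ.loc[name, "exp(coef) lower 95%"]),
                "ci_high": float(summ.loc[name, "exp(coef) upper 95%"]),
                "p": float(summ.loc[name, "p"]),
                "log_likelihood": float(cph.log_likelihood_),
            })
    return pd.DataFrame(rows).set_index("covariate")
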