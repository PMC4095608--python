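"""Kaplan-Meier estimation, the two-group log-rank test, and Cox
proportional-hazards fitting.

The log-rank statistic is computed by a vectorized implementation that can
evaluate many candidate group assignments at once over a fixed cohort; the
exhaustive weight-vector scan depends on this batching.  Kaplan-Meier curves
and Cox models are fitted with lifelines (Efron tie handling, Wald
confidence intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats

__all__ = [
    "KmCurve",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "logrank_chi2_batch",
    "CoxResult",
    "cox_fit",
]


@dataclass
class KmCurve:
    """A product-limit survival curve."""

    event_times: np.ndarray  # distinct times at which the curve changes
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # subjects at risk just before each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step interpolation (S = 1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event, groups=None):
    """Kaplan-Meier curves, optionally per group.

    Subjects censored at an event time are counted at risk for that event
    (standard convention).  Returns a single :class:`KmCurve` or a dict
    keyed by group label.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if groups is None:
        return _km_single(time, event)
    groups = np.asarray(groups)
    out = {}
    for label in pd.unique(groups):
        mask = groups == label
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        out[label] = _km_single(time[mask], event[mask])
    return out


def _km_single(time, event) -> KmCurve:
    if time.size == 0:
        raise ValueError("empty group")
    fitter = KaplanMeierFitter()
    fitter.fit(time, event)
    event_table = fitter.event_table
    rows = event_table[event_table["observed"] > 0]
    return KmCurve(
        event_times=rows.index.to_numpy(dtype=float),
        survival=np.array(
            [float(fitter.survival_function_at_times(t).iloc[0]) for t in rows.index]
        ),
        at_risk=rows["at_risk"].to_numpy(dtype=int),
        censor_times=np.sort(time[event == 0]),
    )


def _logrank_moments(time, event, group_matrix):
    """Observed, expected and hypergeometric variance of group-1 events for a
    batch of 0/1 group assignments (columns of ``group_matrix``)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    G = np.asarray(group_matrix, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    order = np.argsort(time, kind="stable")
    t_s, e_s, G_s = time[order], event[order], G[order]
    n = t_s.size
    _, first_idx = np.unique(t_s, return_index=True)
    d = np.add.reduceat(e_s, first_idx)
    keep = d > 0
    first_idx, d = first_idx[keep], d[keep]
    n_at_risk = (n - first_idx).astype(float)
    suffix = np.cumsum(G_s[::-1], axis=0)[::-1]
    n1 = suffix[first_idx]  # (n_event_times, B)
    if len(first_idx):
        d1 = np.add.reduceat(G_s * e_s[:, None], first_idx, axis=0)
    else:
        d1 = np.zeros((0, G.shape[1]))
    frac = n1 / n_at_risk[:, None]
    expected = d[:, None] * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        tie_factor = np.where(n_at_risk > 1, (n_at_risk - d) / (n_at_risk - 1), 0.0)
    variance = d[:, None] * frac * (1.0 - frac) * tie_factor[:, None]
    return d1.sum(axis=0), expected.sum(axis=0), variance.sum(axis=0)


def logrank_chi2_batch(time, event, group_matrix, signed: bool = False) -> np.ndarray:
    """Log-rank chi-square (1 df) for each column of a 0/1 group matrix.

    With ``signed=True`` the chi-square carries the sign of (observed -
    expected) group-1 events: negative when group 1 (the High-score group)
    has fewer events than expected, i.e. better survival.
    """
    observed, expected, variance = _logrank_moments(time, event, group_matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(variance > 0, (observed - expected) ** 2 / variance, 0.0)
    if signed:
        chi2 = chi2 * np.sign(observed - expected)
    return chi2


@dataclass
class LogrankResult:
    chi_square: float
    p: float
    observed: dict
    expected: dict

    @property
    def degrees_of_freedom(self) -> int:
        return 1


def logrank_test(time, event, group) -> LogrankResult:
    """Standard two-group log-rank test (hypergeometric variance at each
    distinct event time; invariant under swapping the group labels).

    ``group`` may hold any two labels; with zero events overall the
    statistic is 0 and p = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {list(labels)}")
    g1 = (group == labels[1]).astype(float)
    if event.sum() == 0:
        total = {labels[0]: 0.0, labels[1]: 0.0}
        return LogrankResult(0.0, 1.0, total, dict(total))
    observed, expected, variance = _logrank_moments(time, event, g1[:, None])
    o1, e1, v = float(observed[0]), float(expected[0]), float(variance[0])
    total_events = float(event.sum())
    chi2 = (o1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    return LogrankResult(
        chi_square=float(chi2),
        p=p,
        observed={labels[0]: total_events - o1, labels[1]: o1},
        expected={labels[0]: total_events - e1, labels[1]: e1},
    )


@dataclass
class CoxResult:
    """Per-covariate estimates of a proportional-hazards fit."""

    summary: pd.DataFrame  # beta, hazard_ratio, ci_low, ci_high, p per covariate
    log_likelihood: float
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])


def cox_fit(time, event, covariates: pd.DataFrame, ties: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CIs).

    Raises on zero events, on a constant covariate, and on monotone partial
    likelihood (perfect separation), identifying the offending covariate.
    """
    covariates = pd.DataFrame(covariates)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    df = covariates.copy()
    df["__time"] = time
    df["__event"] = event
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            fitter.fit(
                df, duration_col="__time", event_col="__event",
                fit_options={"step_size": 0.5},
            )
    except (ConvergenceError, ConvergenceWarning) as exc:
        raise ValueError(
            f"Cox fit failed (monotone likelihood / non-convergence): {exc}"
        ) from None
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        n=int(len(df)),
        n_events=int(event.sum()),
    )
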