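"""Pre-modelling proportional-hazards screens and nonparametric benchmarks.

Before any network model is fitted, each trial is screened individually:
a Cox partial-likelihood fit per trial, a Schoenfeld-residual test of PH
against a linear-in-ln(t) alternative (matching the model's
treatment-ln(time) interaction), the chi-square pooling of those tests across
trials, and the Nelson-Aalen estimate of the cumulative hazard used as the
fit-quality benchmark for the spline baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NAEstimate",
    "SchoenfeldResult",
    "nelson_aalen",
    "cox_fit",
    "schoenfeld_test",
    "pooled_schoenfeld",
    "spline_vs_na",
]


@dataclass(frozen=True)
class NAEstimate:
    """Nelson-Aalen step-function estimate of the cumulative hazard.

    ``times`` are the distinct event times, ``H`` the cumulative hazard
    H(t) = sum_{t_i <= t} d_i / n_i and ``variance`` its estimated variance.
    """

    times: np.ndarray
    H: np.ndarray
    variance: np.ndarray

    def log_H(self) -> np.ndarray:
        return np.log(self.H)

    def at(self, t: float) -> float:
        """Step-function evaluation H(t)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if i < 0 else float(self.H[i])


def nelson_aalen(times, events) -> NAEstimate:
    """Nelson-Aalen estimator with d/n increments at distinct event times."""
    from lifelines import NelsonAalenFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.any(events == 1):
        warnings.warn("no events: Nelson-Aalen estimate is empty")
        return NAEstimate(np.array([]), np.array([]), np.array([]))
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(times, event_observed=events)
    ch = naf.cumulative_hazard_.iloc[:, 0]
    var = naf._cumulative_sq.reindex(ch.index).ffill().fillna(0.0)
    inc = ch.diff().fillna(ch)
    keep = inc.values > 0
    return NAEstimate(times=ch.index.values[keep].astype(float),
                      H=ch.values[keep], variance=np.asarray(var)[keep])


def cox_fit(trial_data, reference: str | None = None):
    """Cox partial-likelihood fit of a two-arm trial (Efron tie handling).

    Returns ``(logHR, se, fitter)``; the log hazard ratio is for the
    non-reference arm vs the reference (default reference: the
    lexicographically first arm label).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = getattr(trial_data, "df", trial_data).copy()
    arms = sorted(set(df["treatment"]))
    if len(arms) != 2:
        raise ValueError(f"cox_fit expects a binary treatment, got arms {arms}")
    if reference is not None:
        if reference not in arms:
            raise ValueError(f"reference {reference!r} not an arm of this trial")
        arms = [reference] + [a for a in arms if a != reference]
    for arm in arms:
        sub = df[df["treatment"] == arm]
        if not (sub["event"] == 1).any():
            raise ValueError(f"arm {arm!r} has no events; Cox fit not identified")
    work = pd.DataFrame({
        "time": df["time"].astype(float),
        "event": df["event"].astype(int),
        "x": (df["treatment"] == arms[1]).astype(float),
    })
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(work, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-9})
    except ConvergenceError as err:
        raise RuntimeError(
            "monotone partial likelihood (complete separation of event orders)"
        ) from err
    cph._rpnma_training_frame = work
    return float(cph.params_["x"]), float(cph.standard_errors_["x"]), cph


def schoenfeld_test(trial_data, reference: str | None = None,
                    time_transform: str = "log"):
    """Score test of PH from scaled Schoenfeld residuals, 1 df.

    The default ln(t) time transform matches the model's alternative of a
    hazard ratio drifting linearly in ln time; a Kaplan-Meier rank transform
    is available via ``time_transform='km'``.
    """
    from lifelines.statistics import proportional_hazard_test

    df = getattr(trial_data, "df", trial_data)
    if int((df["event"] == 1).sum()) < 3:
        raise ValueError("need >= 3 events for the Schoenfeld residual test")
    _, _, cph = cox_fit(trial_data, reference)
    res = proportional_hazard_test(cph, cph._rpnma_training_frame,
                                   time_transform=time_transform)
    chi2 = float(np.asarray(res.summary["test_statistic"]).ravel()[0])
    p = float(np.asarray(res.summary["p"]).ravel()[0])
    return chi2, 1, p


@dataclass(frozen=True)
class SchoenfeldResult:
    per_trial: pd.DataFrame  # trial, chi2, df, p
    pooled_chi2: float
    pooled_df: int
    pooled_p: float


def pooled_schoenfeld(per_trial: dict) -> SchoenfeldResult:
    """Pool independent per-trial Schoenfeld chi-squares by addition.

    ``per_trial`` maps trial_id -> (chi2, df, p); the pooled statistic is the
    sum on df equal to the number of trials.
    """
    if not per_trial:
        raise ValueError("no per-trial results to pool")
    rows = [{"trial": tid, "chi2": c, "df": d, "p": p}
            for tid, (c, d, p) in per_trial.items()]
    total = float(sum(r["chi2"] for r in rows))
    k = len(rows)
    return SchoenfeldResult(per_trial=pd.DataFrame(rows), pooled_chi2=total,
                            pooled_df=k, pooled_p=float(stats.chi2.sf(total, k)))


def spline_vs_na(chains, trial_id, na: NAEstimate) -> pd.DataFrame:
    """Overlay the posterior spline log cumulative hazard on the Nelson-Aalen
    estimate at its step times (Figure-style diagnostic data).

    Returns a tidy frame (trial, time, na_H, model_median, model_lo, model_hi,
    inside) whose ``inside`` column marks NA points covered by the 95%
    credible band; the coverage fraction is stored in ``df.attrs['coverage']``.
    Step times beyond the boundary knots are evaluated by the spline's linear
    tails — extrapolation is part of the contract, not an error.
    """
    if na.times.size == 0:
        out = pd.DataFrame(columns=["trial", "time", "na_H", "model_median",
                                    "model_lo", "model_hi", "inside"])
        out.attrs["coverage"] = np.nan
        return out
    td = next(t for t in chains.mdata.trials if t.trial_id == trial_id)
    X, _ = td.basis.evaluate(np.log(na.times))
    sl = chains.index.gamma_sl[trial_id]
    gam = chains.draws[:, :, sl].reshape(-1, sl.stop - sl.start)
    eta = gam @ X.T  # (draws, times); baseline (reference-arm) log cumulative hazard
    lo, med, hi = np.percentile(eta, [2.5, 50.0, 97.5], axis=0)
    ln_na = np.log(na.H)
    inside = (ln_na >= lo) & (ln_na <= hi)
    out = pd.DataFrame({
        "trial": trial_id, "time": na.times, "na_H": na.H,
        "model_median": np.exp(med), "model_lo": np.exp(lo),
        "model_hi": np.exp(hi), "inside": inside,
    })
    out.attrs["coverage"] = float(inside.mean())
    return out
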