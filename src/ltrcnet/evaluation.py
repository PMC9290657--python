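"""Absolute-risk prediction and evaluation for LTRC Cox models.

Provides the Breslow step estimator of the cumulative baseline hazard,
survival-curve prediction S(t|x) = exp(-H0(t) * exp(x'b)), the
Kaplan-Meier estimator with optional delayed entry, Harrell's C-index,
and decile calibration curves (mean predicted survival vs KM-observed
survival within bins of predicted risk).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_concordance

from .coxnet import _RiskStructure
from .data import LTRCDataset

#: Bins smaller than this are flagged in calibration output.
SMALL_BIN = 10


@dataclasses.dataclass
class BaselineHazard:
    """Breslow estimate of the cumulative baseline hazard at event times."""

    times: np.ndarray
    cumhaz: np.ndarray
    adjust: bool

    def at(self, eval_times) -> np.ndarray:
        """Right-continuous step interpolation H0(t) = sum_{t_i <= t} dH_i."""
        eval_times = np.asarray(eval_times, dtype=float)
        if np.any(eval_times < 0):
            raise ValueError("evaluation times must be nonnegative")
        idx = np.searchsorted(self.times, eval_times, side="right")
        padded = np.concatenate(([0.0], self.cumhaz))
        return padded[idx]


def breslow_baseline(dataset: LTRCDataset, beta, adjust: bool = True) -> BaselineHazard:
    """Breslow baseline cumulative hazard given fitted coefficients.

    Increments are d_i / sum_{j in R*_i} exp(x_j' b) at each unique event
    time, with the risk set per the ``adjust`` flag.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    eta = dataset.predictors @ beta
    work = _RiskStructure(dataset.time, dataset.entry, dataset.event, adjust)
    # risk-set sums of exp(eta) at each event time; recentre then undo so
    # the baseline is anchored at x = 0 rather than the cohort mean
    shift = eta.mean()
    r = np.exp(eta - shift)
    S = work._suffix(r[work.y_order])[work.pos_y]
    if adjust:
        S = S - work._suffix(r[work.v_order])[work.pos_v]
        np.maximum(S, 1e-300, out=S)
    increments = work.d / (S * np.exp(shift))
    return BaselineHazard(times=work.t.copy(), cumhaz=np.cumsum(increments), adjust=adjust)


def predict_survival(baseline: BaselineHazard, beta, X_new, eval_times) -> np.ndarray:
    """Survival probabilities S(t|x) = exp(-H0(t) exp(x'b)).

    Returns an ``n_new x n_times`` matrix; rows are nonincreasing in t and
    lie in [0, 1].
    """
    beta = np.asarray(beta, dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new.reshape(1, -1)
    H = baseline.at(eval_times)
    risk = np.exp(X_new @ beta)
    return np.exp(-np.outer(risk, H))


@dataclasses.dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, eval_times) -> np.ndarray:
        eval_times = np.asarray(eval_times, dtype=float)
        idx = np.searchsorted(self.times, eval_times, side="right")
        padded = np.concatenate(([1.0], self.survival))
        return padded[idx]

    def __call__(self, eval_times) -> np.ndarray:
        return self.at(eval_times)


def km_estimator(times, events, entries=None) -> KaplanMeierCurve:
    """Kaplan-Meier estimator, optionally adjusted for delayed entry.

    With ``entries`` supplied, the at-risk count at event time t_i is
    #{j : entry_j < t_i <= time_j}; subjects contribute only after their
    entry time, which removes the immortal-time bias of the naive
    estimator on left-truncated data.  Without entries, the standard
    product-limit estimator is returned.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if entries is None:
        entries = np.zeros_like(times)
    else:
        entries = np.asarray(entries, dtype=float)
        if np.any(times <= entries):
            raise ValueError("times must exceed entries")
    ev = events.astype(bool)
    if not ev.any():
        return KaplanMeierCurve(times=np.empty(0), survival=np.empty(0))
    t, d = np.unique(times[ev], return_counts=True)
    times_sorted = np.sort(times)
    entries_sorted = np.sort(entries)
    n = len(times)
    n_out = np.searchsorted(times_sorted, t, side="left")  # y_j < t_i
    n_not_in = n - np.searchsorted(entries_sorted, t, side="left")  # v_j >= t_i
    at_risk = n - n_out - n_not_in
    surv = np.cumprod(1.0 - d / np.maximum(at_risk, 1))
    surv[at_risk < d] = 0.0  # degenerate guard; cannot occur for valid input
    return KaplanMeierCurve(times=t, survival=surv)


def concordance(times, events, risk_scores) -> float:
    """Harrell's C-index from risk scores (higher score = worse prognosis).

    Pairs are comparable under right censoring when the shorter time ends
    in an event; tied risk scores count 1/2.  Entry times play no role in
    pair formation (standard Harrell definition).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk_scores = np.asarray(risk_scores, dtype=float)
    try:
        # lifelines scores "higher prediction = longer survival"
        return float(_lifelines_concordance(times, -risk_scores, events))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs for the C-index") from exc


def calibration_curve(
    pred: np.ndarray,
    times,
    events,
    eval_times,
    n_bins: int = 10,
    entries=None,
) -> pd.DataFrame:
    """Binned predicted-vs-observed survival at each evaluation time.

    At each time, subjects are ranked by predicted survival probability and
    cut into ``n_bins`` equal-count bins (ties broken by stable sort
    order; bin 1 = lowest predicted survival).  Each row reports the mean
    predicted probability and the KM estimate (entry-adjusted iff
    ``entries`` is supplied) evaluated at that time within the bin.  Bins
    smaller than 10 subjects, and bins whose KM step ends before the
    evaluation time (value carried forward from the last step), are
    flagged.
    """
    pred = np.asarray(pred, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    eval_times = np.asarray(eval_times, dtype=float)
    if pred.ndim == 1:
        pred = pred.reshape(-1, 1)
    n = len(times)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} subjects, got {n}")
    rows = []
    for ti, t in enumerate(eval_times):
        order = np.argsort(pred[:, ti], kind="stable")
        for b, idx in enumerate(np.array_split(order, n_bins), start=1):
            sub_entries = None if entries is None else np.asarray(entries)[idx]
            km = km_estimator(times[idx], events[idx], sub_entries)
            observed = float(km.at(t))
            beyond = km.times.size == 0 or t > float(np.max(times[idx]))
            rows.append(
                {
                    "eval_time": float(t),
                    "bin": b,
                    "mean_predicted": float(pred[idx, ti].mean()),
                    "km_observed": observed,
                    "n_bin": int(len(idx)),
                    "flagged": bool(beyond or len(idx) < SMALL_BIN),
                }
            )
    return pd.DataFrame(rows)


def plot_calibration(table: pd.DataFrame, ax=None):
    """Predicted-vs-observed scatter with a 45-degree reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for t, grp in table.groupby("eval_time"):
        ax.scatter(grp["mean_predicted"], grp["km_observed"], label=f"t = {t:g}")
    ax.plot([0, 1], [0, 1], color="black", lw=1)
    ax.set_xlabel("Predicted survival probability")
    ax.set_ylabel("Observed survival probability")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
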