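"""GLM activation mapping and task-minus-rest activation integrals.

Each channel's Δhbo series is regressed on one HRF-convolved boxcar per
condition plus an intercept and a linear drift.  Per-channel t statistics on
the condition amplitudes locate activated channels; the activation integral
(trapezoidal integral of Δhbo over each task window minus the duration-
matched integral over the immediately preceding rest window, averaged over
blocks) quantifies activation intensity on the concentration x time scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hrf import double_gamma_hrf
from .recording import Event, HemoglobinSeries

__all__ = ["DesignMatrix", "ActivationResult", "build_design", "fit_glm", "activation_integral"]

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    X: np.ndarray                 # (n, k)
    names: list[str]              # column names; condition columns first
    conditions: list[str]
    t: np.ndarray

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


def _merge_events(events: list[Event]) -> list[Event]:
    """Merge overlapping events of the same condition (with a warning)."""
    out: list[Event] = []
    by_cond: dict[str, list[Event]] = {}
    for ev in events:
        by_cond.setdefault(ev.condition, []).append(ev)
    for cond, evs in by_cond.items():
        evs = sorted(evs, key=lambda e: e.onset)
        merged = [evs[0]]
        for ev in evs[1:]:
            last = merged[-1]
            if ev.onset < last.onset + last.duration:
                logger.warning("overlapping %s events merged at t=%.1f s", cond, ev.onset)
                end = max(last.onset + last.duration, ev.onset + ev.duration)
                merged[-1] = Event(last.onset, end - last.onset, cond)
            else:
                merged.append(ev)
        out.extend(merged)
    return sorted(out, key=lambda e: e.onset)


def build_design(
    events: list[Event],
    t: np.ndarray,
    hrf_kwargs: dict | None = None,
) -> DesignMatrix:
    """HRF-convolved boxcar regressor per condition + intercept + drift.

    Each condition regressor is normalized to peak 1 so the fitted amplitude
    is on the scale of the data.  The drift column is time rescaled to
    [-0.5, 0.5] (orthogonal in mean to the intercept).
    """
    t = np.asarray(t, dtype=float)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    dt = float(np.median(np.diff(t)))
    end = t[-1] + dt
    for ev in events:
        if ev.onset < t[0] or ev.onset + ev.duration > end + dt:
            raise ValueError(f"event {ev} outside the record")
    events = _merge_events(events)
    conditions: list[str] = []
    for ev in events:
        if ev.condition not in conditions:
            conditions.append(ev.condition)

    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt), **(hrf_kwargs or {}))
    cols, names = [], []
    for cond in conditions:
        box = np.zeros(n)
        for ev in events:
            if ev.condition != cond:
                continue
            i0 = int(round((ev.onset - t[0]) / dt))
            i1 = min(int(round((ev.onset + ev.duration - t[0]) / dt)), n)
            box[i0:i1] = 1.0
        reg = np.convolve(box, hrf)[:n]
        peak = np.abs(reg).max()
        if peak > 0:
            reg = reg / peak
        cols.append(reg)
        names.append(cond)
    cols.append(np.ones(n))
    names.append("intercept")
    drift = (t - t[0]) / (t[-1] - t[0]) - 0.5
    cols.append(drift)
    names.append("drift")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns {names})")
    return DesignMatrix(X=X, names=names, conditions=conditions, t=t)


@dataclass
class ActivationResult:
    conditions: list[str]
    beta: np.ndarray              # (n_ch, n_cond)
    se: np.ndarray                # (n_ch, n_cond)
    t_stat: np.ndarray            # (n_ch, n_cond)
    p_value: np.ndarray           # (n_ch, n_cond)
    dof: int
    activation_integral: np.ndarray | None = None   # (n_ch, n_cond)

    def to_frame(self, channel_regions: list[str] | None = None) -> pd.DataFrame:
        n_ch = self.beta.shape[0]
        rows = []
        for c, cond in enumerate(self.conditions):
            for k in range(n_ch):
                rows.append(dict(
                    condition=cond, channel=k,
                    region=channel_regions[k] if channel_regions else None,
                    beta=self.beta[k, c], se=self.se[k, c],
                    t=self.t_stat[k, c], p=self.p_value[k, c],
                    integral=(self.activation_integral[k, c]
                              if self.activation_integral is not None else np.nan),
                ))
        return pd.DataFrame(rows)


def fit_glm(h: HemoglobinSeries | np.ndarray, design: DesignMatrix) -> ActivationResult:
    """Ordinary least squares per channel with classical t statistics.

    ``h`` may be a HemoglobinSeries (its Δhbo is analyzed) or a plain
    (n_samples, n_channels) array.  t = beta / SE(beta) with n - k residual
    degrees of freedom and two-sided p values.
    """
    Y = h.dhbo if isinstance(h, HemoglobinSeries) else np.asarray(h, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"{Y.shape[0]} samples in data but {X.shape[0]} rows in design")
    n, k = X.shape
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough samples for the design")
    if np.linalg.matrix_rank(X) < k:
        r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [design.names[i] for i in np.flatnonzero(r_diag < 1e-10 * r_diag.max())]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ X.T @ Y                       # (k, n_ch)
    resid = Y - X @ beta_all
    sigma2 = (resid**2).sum(axis=0) / dof              # (n_ch,)
    se_all = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))   # (k, n_ch)
    nc = design.n_conditions
    beta = beta_all[:nc].T
    se = se_all[:nc].T
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * sps.t.sf(np.abs(t_stat), dof)
    return ActivationResult(
        conditions=list(design.conditions), beta=beta, se=se,
        t_stat=t_stat, p_value=p, dof=dof,
    )


def activation_integral(
    h: HemoglobinSeries,
    events: list[Event] | None = None,
    min_rest_s: float = 5.0,
) -> tuple[np.ndarray, list[str]]:
    """Task-minus-rest integral of Δhbo per channel per condition.

    For each block: trapezoidal integral over the task window minus the
    integral over the window of equal length immediately preceding the onset
    (the rest baseline).  If the available rest gap is shorter than the task
    both windows are shortened to the gap; blocks with less than
    ``min_rest_s`` of rest are skipped with a warning.  Block values are
    averaged within condition.  Returns ((n_ch, n_cond) array, conditions).
    """
    events = sorted(h.events if events is None else events, key=lambda e: e.onset)
    conditions: list[str] = []
    for ev in events:
        if ev.condition not in conditions:
            conditions.append(ev.condition)
    n_ch = h.n_channels
    sums = np.zeros((n_ch, len(conditions)))
    counts = np.zeros(len(conditions))
    fs = h.rate
    prev_end = h.t[0]
    for ev in events:
        gap = ev.onset - prev_end
        win = min(ev.duration, gap)
        if win < min_rest_s:
            logger.warning("block %s at %.1f s: only %.1f s rest precedes it; skipped",
                           ev.condition, ev.onset, gap)
            prev_end = ev.onset + ev.duration
            continue
        i_on = int(round((ev.onset - h.t[0]) * fs))
        n_win = int(round(win * fs))
        task = h.dhbo[i_on : i_on + n_win + 1]
        rest = h.dhbo[i_on - n_win : i_on + 1]
        val = np.trapezoid(task, dx=1.0 / fs, axis=0) - np.trapezoid(rest, dx=1.0 / fs, axis=0)
        c = conditions.index(ev.condition)
        sums[:, c] += val
        counts[c] += 1
        prev_end = ev.onset + ev.duration
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, conditions
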