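"""Circle-drawing kinematics.

Trajectories are converted from Cartesian to polar coordinates about the
guide-circle center, and four per-trial metrics quantify tracing quality:

* SDR  — standard deviation of the sample radii (trajectory variability),
* RE   — RMS deviation of the radii from the guide radius r_o (position error),
* SDAV — standard deviation of the instantaneous angular velocity,
* AVE  — RMS deviation of the angular velocity from the guide velocity w_o.

All four use the population form (divisor n).  Lower values mean steadier,
more accurate tracing; RE and AVE are referenced to the displayed guide
circle, which is a known task parameter rather than a fitted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryTrace",
    "PolarTrace",
    "KinematicMetrics",
    "to_polar",
    "radius_sd",
    "radius_error",
    "angvel_sd",
    "angvel_error",
    "compute_metrics",
    "trim_trace",
    "fit_circle",
    "metrics_table",
]


@dataclass
class TrajectoryTrace:
    """Time-stamped planar finger positions for one trial of one hand."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hand: str                           # "left" | "right"
    condition: str
    center: tuple[float, float] = (0.0, 0.0)
    guide_radius: float = 1.0           # r_o, length units of the tablet
    guide_angular_velocity: float = 1.0  # w_o, rad/s; sign encodes direction
    subject: str | int | None = None
    trial: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shape")
        if self.t.size >= 2 and np.diff(self.t).min() <= 0:
            raise ValueError("t must be strictly increasing")
        if self.hand not in ("left", "right"):
            raise ValueError("hand must be 'left' or 'right'")
        if self.guide_radius <= 0:
            raise ValueError("guide_radius must be positive")
        if self.guide_angular_velocity == 0:
            raise ValueError("guide_angular_velocity must be nonzero")

    @property
    def n(self) -> int:
        return self.t.size


@dataclass
class PolarTrace:
    """Polar representation of a trajectory about the guide center."""

    t: np.ndarray
    r: np.ndarray          # sample radii r_i, >= 0
    theta: np.ndarray      # unwrapped angle, rad
    w: np.ndarray          # instantaneous angular velocity w_i, rad/s

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def mean_radius(self) -> float:
        return float(self.r.mean())

    @property
    def mean_angular_velocity(self) -> float:
        return float(self.w.mean())


@dataclass(frozen=True)
class KinematicMetrics:
    sdr: float
    re: float
    sdav: float
    ave: float
    n: int


def trim_trace(trace: TrajectoryTrace, lead_s: float = 0.5, trail_s: float = 0.5) -> TrajectoryTrace:
    """Drop a leading/trailing window per trial.

    Removes the redundant samples produced around task-mode switches.  The
    trim windows are configurable; trimming never reduces a trial below two
    samples (in that case the trace is returned unchanged).
    """
    if lead_s < 0 or trail_s < 0:
        raise ValueError("trim windows must be non-negative")
    t0, t1 = trace.t[0] + lead_s, trace.t[-1] - trail_s
    keep = (trace.t >= t0) & (trace.t <= t1)
    if keep.sum() < 2:
        return trace
    return TrajectoryTrace(
        t=trace.t[keep], x=trace.x[keep], y=trace.y[keep],
        hand=trace.hand, condition=trace.condition, center=trace.center,
        guide_radius=trace.guide_radius,
        guide_angular_velocity=trace.guide_angular_velocity,
        subject=trace.subject, trial=trace.trial, meta=dict(trace.meta),
    )


def to_polar(trace: TrajectoryTrace) -> PolarTrace:
    """Convert a trajectory to polar coordinates about the guide center.

    The angle is unwrapped, and the angular velocity is the finite-difference
    derivative of the unwrapped angle (central differences in the interior,
    one-sided at the endpoints), so ``w`` has one value per sample.
    """
    if trace.n < 2:
        raise ValueError("need at least 2 samples to compute angular velocity")
    cx, cy = trace.center
    dx, dy = trace.x - cx, trace.y - cy
    r = np.hypot(dx, dy)
    theta = np.unwrap(np.arctan2(dy, dx))
    w = np.gradient(theta, trace.t)
    return PolarTrace(t=trace.t, r=r, theta=theta, w=w)


def _rms_about(values: np.ndarray, reference: float) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty trace")
    return float(np.sqrt(np.mean((values - reference) ** 2)))


def radius_sd(p: PolarTrace) -> float:
    """SDR: population standard deviation of the sample radii."""
    if p.n < 2:
        raise ValueError("need at least 2 samples")
    return _rms_about(p.r, p.mean_radius)


def radius_error(p: PolarTrace, r_o: float) -> float:
    """RE: RMS deviation of the sample radii from the guide radius r_o."""
    if r_o <= 0:
        raise ValueError("guide radius r_o must be positive")
    return _rms_about(p.r, r_o)


def angvel_sd(p: PolarTrace) -> float:
    """SDAV: population standard deviation of the angular velocity."""
    if p.n < 2:
        raise ValueError("need at least 2 samples")
    return _rms_about(p.w, p.mean_angular_velocity)


def angvel_error(p: PolarTrace, w_o: float) -> float:
    """AVE: RMS deviation of the signed angular velocity from w_o."""
    if w_o == 0:
        raise ValueError("guide angular velocity w_o must be nonzero")
    return _rms_about(p.w, w_o)


def compute_metrics(trace: TrajectoryTrace, trim_s: float | None = None) -> KinematicMetrics:
    """All four metrics for one trial, referenced to the trace's guide circle.

    ``trim_s`` optionally trims that many seconds from each end first.
    """
    if trim_s:
        trace = trim_trace(trace, trim_s, trim_s)
    p = to_polar(trace)
    return KinematicMetrics(
        sdr=radius_sd(p),
        re=radius_error(p, trace.guide_radius),
        sdav=angvel_sd(p),
        ave=angvel_error(p, trace.guide_angular_velocity),
        n=p.n,
    )


def fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit: returns (cx, cy, radius).

    Exploratory alternative to the known guide center; not used by the
    default metric path.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("circle fit needs at least 3 points")
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    radius = float(np.sqrt(c + cx**2 + cy**2))
    return float(cx), float(cy), radius


def metrics_table(traces: list[TrajectoryTrace], trim_s: float | None = 0.5) -> pd.DataFrame:
    """Tidy per-trial metrics: subject, condition, hand, trial, sdr, re, sdav, ave, n."""
    rows = []
    for tr in traces:
        m = compute_metrics(tr, trim_s=trim_s)
        rows.append(
            dict(subject=tr.subject, condition=tr.condition, hand=tr.hand,
                 trial=tr.trial, sdr=m.sdr, re=m.re, sdav=m.sdav, ave=m.ave, n=m.n)
        )
    return pd.DataFrame(rows)
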