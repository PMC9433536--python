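"""fNIRS preprocessing: optics inversion, artifact repair, band filtering.

The modified Beer-Lambert law relates optical-density change at wavelength
lambda to chromophore concentration changes:

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF(lambda)

with source-detector distance ``d`` and differential pathlength factor DPF.
With three wavelengths and two chromophores the system is solved per sample
by least squares.  Motion artifacts are flagged where a centered moving
standard deviation exceeds a threshold, repaired by cubic-spline
interpolation over clean neighbors, and physiological nuisance is removed by
a zero-phase Butterworth band-pass (0.021-0.6 Hz) plus a band-stop over the
Mayer-wave band (0.08-0.12 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .recording import HemoglobinSeries, NirsRecording

__all__ = [
    "EXTINCTION_CM_PER_M",
    "ArtifactMask",
    "beer_lambert",
    "beer_lambert_forward",
    "detect_artifacts",
    "repair_spline",
    "apply_filters",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)

#: Molar extinction coefficients (cm^-1 M^-1) of oxy-/deoxyhemoglobin at the
#: instrument wavelengths, from the standard compiled in-vitro tables
#: (Gratzer/Prahl lineage).  Keys are wavelengths in nm, values (HbO, HbR).
EXTINCTION_CM_PER_M: dict[float, tuple[float, float]] = {
    740.0: (446.0, 1115.88),
    808.0: (855.2, 735.4),
    850.0: (1058.0, 691.32),
}


def _extinction_matrix(
    wavelengths: tuple[float, ...],
    table: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    table = EXTINCTION_CM_PER_M if table is None else table
    rows = []
    for wl in wavelengths:
        if wl not in table:
            raise ValueError(f"no extinction coefficients for {wl} nm; extend the table")
        rows.append(table[wl])
    E = np.asarray(rows, dtype=float)
    if len(set(wavelengths)) < 2:
        raise ValueError("need >= 2 distinct wavelengths (singular extinction system)")
    return E


def _pathlength_matrix(
    wavelengths: tuple[float, ...],
    dpf: float | np.ndarray,
    distance_mm: float,
    table=None,
) -> np.ndarray:
    """A (n_wl x 2) with dOD = A @ [dHbO, dHbR] in micromolar units."""
    E = _extinction_matrix(wavelengths, table)
    dpf = np.broadcast_to(np.asarray(dpf, dtype=float), (len(wavelengths),))
    if np.any(dpf <= 0) or distance_mm <= 0:
        raise ValueError("DPF and distance must be positive")
    d_cm = distance_mm / 10.0
    # E is per mol/L; concentrations are expressed in umol/L
    return E * 1e-6 * (dpf * d_cm)[:, None]


def beer_lambert_forward(
    dhbo: np.ndarray,
    dhbr: np.ndarray,
    wavelengths: tuple[float, ...],
    dpf: float | np.ndarray = 6.0,
    distance_mm: float = 30.0,
    table=None,
) -> np.ndarray:
    """Forward model: (n, n_ch) concentration changes -> (n, n_ch, n_wl) dOD."""
    A = _pathlength_matrix(wavelengths, dpf, distance_mm, table)
    conc = np.stack([dhbo, dhbr], axis=-1)           # (n, n_ch, 2)
    return conc @ A.T                                 # (n, n_ch, n_wl)


def beer_lambert(
    rec: NirsRecording,
    dpf: float | np.ndarray = 6.0,
    distance_mm: float = 30.0,
    table=None,
) -> HemoglobinSeries:
    """Invert the modified Beer-Lambert law by per-sample least squares.

    Returns hemoglobin concentration changes in micromolar.
    """
    if rec.signal_kind != "optical_density":
        raise ValueError("beer_lambert expects an optical_density recording")
    A = _pathlength_matrix(tuple(rec.wavelengths), dpf, distance_mm, table)
    pinv = np.linalg.pinv(A)                          # (2, n_wl)
    conc = rec.channels @ pinv.T                      # (n, n_ch, 2)
    return HemoglobinSeries(
        t=rec.t,
        dhbo=conc[..., 0],
        dhbr=conc[..., 1],
        rate=rec.rate,
        channel_regions=list(rec.channel_regions),
        events=list(rec.events),
        meta=dict(rec.meta),
    )


@dataclass
class ArtifactMask:
    """Boolean per-sample flags plus the merged half-open segments per channel."""

    flagged: np.ndarray                              # (n, n_ch) bool
    segments: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def any_flagged(self) -> bool:
        return bool(self.flagged.any())


def moving_std(x: np.ndarray, window: int, ddof: int = 1) -> np.ndarray:
    """Centered moving standard deviation with edge-truncated windows.

    Vectorized two-pass cumulative-sum evaluation; matches a direct
    per-window computation to floating-point accuracy.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if window < 2:
        raise ValueError("window must be >= 2 samples")
    if window > n:
        raise ValueError("window longer than the record")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    cs = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    cs2 = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x * x, axis=0)])
    cnt = (hi - lo).astype(float)
    if x.ndim > 1:
        cnt = cnt[:, None]
    s1 = cs[hi] - cs[lo]
    s2 = cs2[hi] - cs2[lo]
    var = (s2 - s1 * s1 / cnt) / np.maximum(cnt - ddof, 1.0)
    return np.sqrt(np.maximum(var, 0.0))


def _merge_segments(flags: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, f in enumerate(flags):
        if f and not in_run:
            in_run, start = True, i
        elif not f and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(flags)))
    return out


def detect_artifacts(
    h: HemoglobinSeries,
    window: int = 10,
    threshold: float = 5.0,
    pad_s: float = 0.5,
) -> ArtifactMask:
    """Flag motion artifacts on the Δhbo series.

    A sample is flagged when the centered ``window``-sample moving standard
    deviation strictly exceeds ``threshold`` (in the data's concentration
    units).  Flagged runs are merged and padded by ``pad_s`` seconds on each
    side.
    """
    mstd = moving_std(h.dhbo, window)
    raw = mstd > threshold
    pad = int(round(pad_s * h.rate))
    n, n_ch = raw.shape
    flagged = np.zeros_like(raw)
    segments: dict[int, list[tuple[int, int]]] = {}
    for k in range(n_ch):
        segs = [(max(a - pad, 0), min(b + pad, n)) for a, b in _merge_segments(raw[:, k])]
        merged: list[tuple[int, int]] = []
        for a, b in segs:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        segments[k] = merged
        for a, b in merged:
            flagged[a:b, k] = True
    return ArtifactMask(flagged=flagged, segments=segments)


def repair_spline(h: HemoglobinSeries, mask: ArtifactMask) -> HemoglobinSeries:
    """Replace flagged samples by cubic-spline interpolation over clean data.

    Unflagged samples are untouched.  A flagged segment touching a record
    boundary cannot be interpolated; it is filled by extending the nearest
    clean value (logged).
    """
    out = h.copy()
    for name in ("dhbo", "dhbr"):
        data = getattr(out, name)
        for k in range(h.n_channels):
            bad = mask.flagged[:, k]
            if not bad.any():
                continue
            good = ~bad
            if good.sum() < 4:
                raise ValueError(f"channel {k}: too few clean samples to repair")
            if bad[0] or bad[-1]:
                logger.warning("channel %d: artifact touches record boundary; extending nearest clean value", k)
            inner = bad & (h.t >= h.t[good][0]) & (h.t <= h.t[good][-1])
            if inner.any():
                spl = CubicSpline(h.t[good], data[good, k])
                data[inner, k] = spl(h.t[inner])
            edge = bad & ~inner
            if edge.any():
                lo_t, hi_t = h.t[good][0], h.t[good][-1]
                data[edge & (h.t < lo_t), k] = data[good, k][0]
                data[edge & (h.t > hi_t), k] = data[good, k][-1]
    return out


def _band_sos(rate: float, bandpass: tuple[float, float], bandstop: tuple[float, float] | None,
              bp_order: int = 4, bs_order: int = 2):
    nyq = rate / 2.0
    lo, hi = bandpass
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band-pass edges must satisfy 0 < {lo} < {hi} < Nyquist {nyq}")
    sos_list = [butter(bp_order, [lo, hi], btype="bandpass", fs=rate, output="sos")]
    if bandstop is not None:
        slo, shi = bandstop
        if not (0 < slo < shi < nyq):
            raise ValueError(f"band-stop edges must satisfy 0 < {slo} < {shi} < Nyquist {nyq}")
        sos_list.append(butter(bs_order, [slo, shi], btype="bandstop", fs=rate, output="sos"))
    return sos_list


def apply_filters(
    h: HemoglobinSeries,
    bandpass: tuple[float, float] = (0.021, 0.6),
    bandstop: tuple[float, float] | None = (0.08, 0.12),
    bp_order: int = 4,
    bs_order: int = 2,
) -> HemoglobinSeries:
    """Zero-phase Butterworth band-pass plus Mayer-band band-stop.

    Both filters are applied forward-backward (``sosfiltfilt``), so the
    effective magnitude response is squared and the phase response is zero.
    """
    sos_list = _band_sos(h.rate, bandpass, bandstop, bp_order, bs_order)
    out = h.copy()
    for name in ("dhbo", "dhbr"):
        data = getattr(out, name)
        for sos in sos_list:
            data = sosfiltfilt(sos, data, axis=0)
        setattr(out, name, data)
    return out


def preprocess_recording(
    rec: NirsRecording,
    dpf: float | np.ndarray = 6.0,
    distance_mm: float = 30.0,
    window: int = 10,
    threshold: float = 5.0,
    pad_s: float = 0.5,
    bandpass: tuple[float, float] = (0.021, 0.6),
    bandstop: tuple[float, float] | None = (0.08, 0.12),
) -> tuple[HemoglobinSeries, ArtifactMask]:
    """Full cleaning chain: Beer-Lambert (if optical) -> artifact detection ->
    spline repair -> zero-phase band filtering."""
    if rec.signal_kind == "optical_density":
        h = beer_lambert(rec, dpf=dpf, distance_mm=distance_mm)
    else:
        h = HemoglobinSeries(
            t=rec.t, dhbo=rec.channels, dhbr=np.zeros_like(rec.channels),
            rate=rec.rate, channel_regions=list(rec.channel_regions),
            events=list(rec.events), meta=dict(rec.meta),
        )
    mask = detect_artifacts(h, window=window, threshold=threshold, pad_s=pad_s)
    h = repair_spline(h, mask)
    h = apply_filters(h, bandpass=bandpass, bandstop=bandstop)
    return h, mask
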