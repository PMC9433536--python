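"""Canonical hemodynamic response function.

The same double-gamma kernel is used by the synthetic generator and by the
GLM design builder, so amplitude recovery is an identity check rather than a
model-mismatch exercise.
"""

import numpy as np
from scipy.stats import gamma as _gamma


def double_gamma_hrf(
    t: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Gamma density peaking at ``peak_s`` minus a gamma density peaking at
    ``undershoot_s`` scaled by ``1/undershoot_ratio``; the result is
    normalized so its maximum equals 1.  Negative times map to 0.
    """
    t = np.asarray(t, dtype=float)
    if peak_s <= 0 or undershoot_s <= 0 or undershoot_ratio <= 0:
        raise ValueError("HRF shape parameters must be strictly positive")
    # gamma(shape=a, scale=1) has mode a-1, so shape = peak + 1
    h = _gamma.pdf(t, peak_s + 1.0) - _gamma.pdf(t, undershoot_s + 1.0) / undershoot_ratio
    m = h.max()
    if m > 0:
        h = h / m
    return h
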