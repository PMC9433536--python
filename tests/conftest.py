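import numpy as np
import pytest

from nirsmoco.kinematics import TrajectoryTrace
from nirsmoco.synthetic_data import CohortDesign, NirsGroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trace(rng, n=200, rate=28.5):
    """A noisy circular trace with random guide parameters."""
    r_o = rng.uniform(0.5, 2.0)
    w_o = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 3.0)
    t = np.arange(n) / rate
    theta = w_o * t + rng.normal(0, 0.05, n)
    r = r_o + rng.normal(0, 0.1, n)
    return TrajectoryTrace(
        t=t, x=r * np.cos(theta), y=r * np.sin(theta),
        hand="right", condition="RHCC",
        guide_radius=r_o, guide_angular_velocity=w_o,
    )


@pytest.fixture
def small_design():
    """Two conditions, enough blocks for the LF wavelet analysis."""
    return CohortDesign(n_subjects=1, conditions=("LHCW", "RHCW"),
                        n_blocks_per_condition=4, n_channels=6)


def quiet_nirs_gt(n_channels=6, **kw):
    """Ground truth with all nuisance components off unless requested."""
    defaults = dict(
        n_channels=n_channels, activation_amplitude=0.0, coupling=None,
        cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0, lf_amp=0.0,
        artifact_rate=0.0, noise_sd=0.0,
    )
    defaults.update(kw)
    return NirsGroundTruth(**defaults)
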