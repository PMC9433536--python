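"""Synthetic cohorts with known ground truth.

Emulates a bimanual circle-drawing fNIRS study: 21 subjects perform eight
unilateral/bilateral clockwise/counterclockwise conditions in a block design
(12 s task, 15 s rest, 10 blocks), while a 30-channel recording over six
cortical regions is acquired at 11 Hz and finger trajectories at 28.5 Hz.

Every downstream stage is driven by these generators, so each physiological
and behavioural feature is parameterized with a known ground truth:

* trajectories — guide circle of radius ``r_o`` traversed at ``w_o`` rad/s,
  with controllable radius bias, radius noise and angular-velocity noise;
* hemodynamics — HRF-convolved task boxcars, a shared low-frequency phase
  process mixed into each channel in proportion to the requested coupling
  (the knob that controls phase-locking values), cardiac / respiratory /
  Mayer-wave sinusoids, white noise, and optional spike artifacts;
* optics — the hemoglobin series are pushed through the Beer-Lambert forward
  model so recordings arrive as optical-density changes per wavelength, and
  the preprocessing stage has a real inversion to perform.

All randomness flows from a single seed through ``numpy.random.SeedSequence``;
identical seed and parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hrf import double_gamma_hrf
from .kinematics import TrajectoryTrace
from .recording import Event, HemoglobinSeries, NirsRecording, default_channel_regions

__all__ = [
    "CONDITIONS",
    "CohortDesign",
    "TrajectoryGroundTruth",
    "NirsGroundTruth",
    "SubjectData",
    "Cohort",
    "condition_hands",
    "is_bilateral",
    "is_in_phase",
    "gen_trajectory",
    "gen_hemoglobin",
    "gen_nirs_recording",
    "gen_cohort",
    "contralateral_amplitudes",
    "region_coupling",
    "default_effect_spec",
]

#: The eight task conditions: unilateral left/right hand clockwise (CW) or
#: counterclockwise (CC), and bilateral combinations (C = clockwise,
#: W = counterclockwise; e.g. LCRW = left clockwise + right counterclockwise).
CONDITIONS = ("LHCW", "LHCC", "RHCW", "RHCC", "LCRC", "LWRW", "LCRW", "LWRC")

_CONDITION_HANDS = {
    "LHCW": (("left", "clockwise"),),
    "LHCC": (("left", "counterclockwise"),),
    "RHCW": (("right", "clockwise"),),
    "RHCC": (("right", "counterclockwise"),),
    "LCRC": (("left", "clockwise"), ("right", "clockwise")),
    "LWRW": (("left", "counterclockwise"), ("right", "counterclockwise")),
    "LCRW": (("left", "clockwise"), ("right", "counterclockwise")),
    "LWRC": (("left", "counterclockwise"), ("right", "clockwise")),
}


def condition_hands(condition: str) -> tuple[tuple[str, str], ...]:
    """(hand, direction) pairs active in a condition code."""
    try:
        return _CONDITION_HANDS[condition]
    except KeyError:
        raise ValueError(f"unknown condition code {condition!r}") from None


def is_bilateral(condition: str) -> bool:
    return len(condition_hands(condition)) == 2


def is_in_phase(condition: str) -> bool:
    """True for mirror-symmetric bilateral movements (hands rotate in
    opposite screen directions), False for anti-phase bilateral ones."""
    hands = condition_hands(condition)
    if len(hands) != 2:
        raise ValueError(f"{condition} is not a bilateral condition")
    return hands[0][1] != hands[1][1]


@dataclass(frozen=True)
class CohortDesign:
    """Study design: who, what and at which rates."""

    n_subjects: int = 21
    conditions: tuple[str, ...] = CONDITIONS
    n_blocks_per_condition: int = 10
    task_duration_s: float = 12.0
    rest_duration_s: float = 15.0
    nirs_rate_hz: float = 11.0
    traj_rate_hz: float = 28.5
    n_channels: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition codes must be unique")
        for c in self.conditions:
            condition_hands(c)
        for name in ("n_blocks_per_condition",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("task_duration_s", "rest_duration_s", "nirs_rate_hz", "traj_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TrajectoryGroundTruth:
    """Ground truth for one hand's tracing behaviour."""

    guide_radius: float = 1.0            # r_o, tablet units
    guide_angular_velocity: float = 2.0 * np.pi / 4.0   # w_o rad/s, one lap per 4 s
    radius_bias: float = 0.0             # systematic over/undershoot of the radius
    radius_noise_sd: float = 0.0         # per-sample radial noise
    angvel_noise_sd: float = 0.0         # per-sample angular-velocity noise
    direction: str = "counterclockwise"

    def __post_init__(self):
        if self.guide_radius <= 0:
            raise ValueError("guide_radius must be positive")
        if self.guide_angular_velocity <= 0:
            raise ValueError("guide_angular_velocity is a magnitude; set direction separately")
        if self.radius_noise_sd < 0 or self.angvel_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ValueError("direction must be 'clockwise' or 'counterclockwise'")


def _check_coupling(m: np.ndarray, n_channels: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n_channels, n_channels):
        raise ValueError(f"coupling matrix must be {(n_channels, n_channels)}, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ValueError("coupling matrix must be symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError("coupling matrix must have a zero diagonal")
    if m.min() < 0 or m.max() > 1:
        raise ValueError("coupling entries must lie in [0, 1]")
    return m


@dataclass
class NirsGroundTruth:
    """Ground truth for the hemodynamic generator.

    ``activation_amplitude`` is a per-channel vector (micromolar Δhbo at the
    regressor peak) or a mapping condition -> vector.  ``coupling`` is a
    symmetric zero-diagonal matrix of pairwise low-frequency phase-coupling
    strengths in [0, 1], or a mapping condition -> matrix for task-dependent
    coupling; pairwise targets are realized through per-channel loadings onto
    one shared phase process (exact for rank-one matrices).
    """

    n_channels: int = 30
    activation_amplitude: np.ndarray | dict = 0.5
    coupling: np.ndarray | dict | None = None
    cardiac_freq_hz: float = 1.0
    resp_freq_hz: float = 0.25
    mayer_freq_hz: float = 0.1
    cardiac_amp: float = 0.2
    resp_amp: float = 0.15
    mayer_amp: float = 0.15
    lf_freq_hz: float = 0.05             # carrier of the coupled LF oscillation
    lf_amp: float = 0.5
    phase_jitter: float = 0.3            # rad / sqrt(s), Wiener phase diffusion
    artifact_rate: float = 1.0           # spike events per minute per channel
    artifact_amp: float = 15.0
    noise_sd: float = 0.1
    hbr_ratio: float = -0.3              # Δhbr = hbr_ratio * Δhbo task component

    def __post_init__(self):
        if self.coupling is None:
            self.coupling = np.zeros((self.n_channels, self.n_channels))
        if isinstance(self.coupling, dict):
            self.coupling = {k: _check_coupling(v, self.n_channels) for k, v in self.coupling.items()}
        else:
            self.coupling = _check_coupling(self.coupling, self.n_channels)
        for name in ("cardiac_freq_hz", "resp_freq_hz", "mayer_freq_hz", "lf_freq_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.artifact_rate < 0 or self.phase_jitter < 0:
            raise ValueError("noise_sd, artifact_rate and phase_jitter must be >= 0")

    def amplitude_for(self, condition: str) -> np.ndarray:
        a = self.activation_amplitude
        if isinstance(a, dict):
            a = a.get(condition, 0.0)
        return np.broadcast_to(np.asarray(a, dtype=float), (self.n_channels,)).copy()

    def coupling_for(self, condition: str | None) -> np.ndarray:
        c = self.coupling
        if isinstance(c, dict):
            if condition is not None and condition in c:
                return c[condition]
            return c.get("rest", np.zeros((self.n_channels, self.n_channels)))
        return c


def gen_trajectory(
    gt: TrajectoryGroundTruth,
    duration_s: float,
    rate_hz: float,
    seed: int | np.random.SeedSequence = 0,
    hand: str = "right",
    condition: str = "RHCC",
    center: tuple[float, float] = (0.0, 0.0),
    subject=None,
    trial: int | None = None,
) -> TrajectoryTrace:
    """One trial's trajectory: a noisy circle around ``center``.

    Sample radii are ``guide_radius + radius_bias`` plus white radial noise;
    the angle advances at the signed guide angular velocity plus white
    angular-velocity noise, integrated over time.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration_s * rate_hz))
    if n < 8:
        raise ValueError("duration * rate must give at least 8 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate_hz
    sign = 1.0 if gt.direction == "counterclockwise" else -1.0
    w_o = sign * gt.guide_angular_velocity

    w = np.full(n, w_o)
    if gt.angvel_noise_sd > 0:
        w = w + rng.normal(0.0, gt.angvel_noise_sd, n)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    dt = 1.0 / rate_hz
    theta = theta0 + np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * dt)])

    r = np.full(n, gt.guide_radius + gt.radius_bias)
    if gt.radius_noise_sd > 0:
        r = r + rng.normal(0.0, gt.radius_noise_sd, n)

    cx, cy = center
    return TrajectoryTrace(
        t=t,
        x=cx + r * np.cos(theta),
        y=cy + r * np.sin(theta),
        hand=hand,
        condition=condition,
        center=center,
        guide_radius=gt.guide_radius,
        guide_angular_velocity=w_o,
        subject=subject,
        trial=trial,
        meta={"ground_truth": gt},
    )


def build_events(design: CohortDesign, rng: np.random.Generator | None = None) -> tuple[list[Event], float]:
    """Block schedule: lead-in rest, then per block every condition once
    (order shuffled per block when a generator is given), each task followed
    by a rest period.  Returns (events, total duration)."""
    events: list[Event] = []
    t = design.rest_duration_s  # lead-in rest
    order = list(design.conditions)
    for _ in range(design.n_blocks_per_condition):
        if rng is not None:
            order = list(rng.permutation(design.conditions))
        for cond in order:
            events.append(Event(onset=t, duration=design.task_duration_s, condition=cond))
            t += design.task_duration_s + design.rest_duration_s
    return events, t


def _phase_process(rng: np.random.Generator, n: int, dt: float, freq_hz: float, jitter: float) -> np.ndarray:
    """Unwrapped phase: linear advance at freq_hz plus Wiener diffusion."""
    phase = 2.0 * np.pi * freq_hz * dt * np.arange(n) + rng.uniform(0.0, 2.0 * np.pi)
    if jitter > 0:
        phase = phase + np.cumsum(rng.normal(0.0, jitter * np.sqrt(dt), n))
    return phase


def _channel_loadings(coupling: np.ndarray) -> np.ndarray:
    """Per-channel loading onto the shared LF phase process.

    lambda_k = sqrt(max_j kappa_kj): exact when the requested matrix is
    rank-one (kappa_ij = lambda_i * lambda_j), an upper envelope otherwise.
    """
    return np.sqrt(coupling.max(axis=1, initial=0.0))


def gen_hemoglobin(
    design: CohortDesign,
    gt: NirsGroundTruth,
    seed: int | np.random.SeedSequence = 0,
    channel_regions: list[str] | None = None,
) -> HemoglobinSeries:
    """Synthetic hemoglobin concentration series with known ground truth.

    Each channel's Δhbo is the sum of the HRF-convolved task boxcars scaled
    by that channel's (condition-specific) amplitude, the coupled LF
    oscillation, the three physiological sinusoids with random phases, white
    noise and spike artifacts.  Δhbr mirrors the task component at
    ``hbr_ratio`` with its own (smaller) noise.
    """
    if channel_regions is None:
        channel_regions = default_channel_regions(gt.n_channels)
    if len(channel_regions) != gt.n_channels:
        raise ValueError("channel_regions length must match gt.n_channels")
    rng = np.random.default_rng(seed)
    events, total_s = build_events(design, rng)
    fs = design.nirs_rate_hz
    dt = 1.0 / fs
    n = int(round(total_s * fs)) + 1
    t = np.arange(n) * dt
    n_ch = gt.n_channels

    # HRF kernel sampled at the recording rate, 32 s support
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt))

    task = np.zeros((n, n_ch))
    cond_active: dict[str, np.ndarray] = {}
    for cond in design.conditions:
        box = np.zeros(n)
        active = np.zeros(n, dtype=bool)
        for ev in events:
            if ev.condition != cond:
                continue
            i0 = int(round(ev.onset * fs))
            i1 = min(int(round((ev.onset + ev.duration) * fs)), n)
            box[i0:i1] = 1.0
            active[i0:i1] = True
        cond_active[cond] = active
        reg = np.convolve(box, hrf)[:n]
        peak = reg.max()
        if peak > 0:
            reg = reg / peak
        task += reg[:, None] * gt.amplitude_for(cond)[None, :]

    # condition-dependent per-channel loadings onto the shared LF phase
    lam = np.zeros((n, n_ch))
    if isinstance(gt.coupling, dict):
        lam_rest = _channel_loadings(gt.coupling_for(None))
        lam[:] = lam_rest
        for cond, active in cond_active.items():
            lam[active] = _channel_loadings(gt.coupling_for(cond))
    else:
        lam[:] = _channel_loadings(gt.coupling)

    theta_common = _phase_process(rng, n, dt, gt.lf_freq_hz, gt.phase_jitter)
    lf = np.empty((n, n_ch))
    for k in range(n_ch):
        theta_k = _phase_process(rng, n, dt, gt.lf_freq_hz, gt.phase_jitter)
        phi = lam[:, k] * theta_common + (1.0 - lam[:, k]) * theta_k
        lf[:, k] = gt.lf_amp * np.cos(phi)

    physio = np.zeros((n, n_ch))
    for amp, freq in (
        (gt.cardiac_amp, gt.cardiac_freq_hz),
        (gt.resp_amp, gt.resp_freq_hz),
        (gt.mayer_amp, gt.mayer_freq_hz),
    ):
        if amp == 0:
            continue
        if freq >= fs / 2:  # above Nyquist at this rate; skip rather than alias
            continue
        phases = rng.uniform(0.0, 2.0 * np.pi, n_ch)
        physio += amp * np.sin(2.0 * np.pi * freq * t[:, None] + phases[None, :])

    noise = rng.normal(0.0, gt.noise_sd, (n, n_ch)) if gt.noise_sd > 0 else np.zeros((n, n_ch))

    artifacts = np.zeros((n, n_ch))
    if gt.artifact_rate > 0 and gt.artifact_amp != 0:
        for k in range(n_ch):
            n_events = rng.poisson(gt.artifact_rate * total_s / 60.0)
            for _ in range(n_events):
                pos = rng.integers(0, n)
                width = rng.integers(1, 4)
                sign = rng.choice([-1.0, 1.0])
                artifacts[pos : min(pos + width, n), k] += sign * gt.artifact_amp

    dhbo = task + lf + physio + noise + artifacts
    dhbr = gt.hbr_ratio * (task + artifacts) + rng.normal(0.0, 0.3 * gt.noise_sd + 1e-12, (n, n_ch))
    return HemoglobinSeries(
        t=t, dhbo=dhbo, dhbr=dhbr, rate=fs,
        channel_regions=channel_regions, events=events,
        meta={"ground_truth": gt, "design": design},
    )


def gen_nirs_recording(
    design: CohortDesign,
    gt: NirsGroundTruth,
    seed: int | np.random.SeedSequence = 0,
    channel_regions: list[str] | None = None,
    wavelengths: tuple[float, ...] = (740.0, 808.0, 850.0),
    dpf: float = 6.0,
    distance_mm: float = 30.0,
) -> NirsRecording:
    """Synthetic raw recording: optical-density changes per wavelength.

    Generates hemoglobin series with :func:`gen_hemoglobin` and pushes them
    through the Beer-Lambert forward model, so preprocessing must invert the
    optics to recover them.
    """
    from .preprocess import beer_lambert_forward

    h = gen_hemoglobin(design, gt, seed, channel_regions)
    od = beer_lambert_forward(h.dhbo, h.dhbr, wavelengths, dpf=dpf, distance_mm=distance_mm)
    return NirsRecording(
        t=h.t,
        channels=od,
        signal_kind="optical_density",
        channel_regions=h.channel_regions,
        events=h.events,
        rate=h.rate,
        wavelengths=wavelengths,
        meta={"dpf": dpf, "distance_mm": distance_mm, **h.meta},
    )


@dataclass
class SubjectData:
    subject: int
    trajectories: list[TrajectoryTrace]
    recording: NirsRecording


@dataclass
class Cohort:
    design: CohortDesign
    subjects: list[SubjectData]
    ground_truth: pd.DataFrame


def contralateral_amplitudes(
    condition: str,
    base: float = 0.5,
    n_channels: int = 30,
    channel_regions: list[str] | None = None,
    ip_nondominant_scale: float = 0.5,
) -> np.ndarray:
    """Per-channel activation amplitudes following contralateral control.

    Each active hand drives the motor cortex of the opposite hemisphere
    (left hand -> RMC, right hand -> LMC).  During mirror-symmetric (in-phase)
    bilateral movement the non-dominant hemisphere's motor cortex receives
    ``ip_nondominant_scale`` of the base amplitude, reflecting
    dominant-hemisphere-led control; anti-phase movement drives both sides
    equally.
    """
    regions = channel_regions or default_channel_regions(n_channels)
    amp = np.zeros(len(regions))
    hands = condition_hands(condition)
    bilateral = len(hands) == 2
    for hand, _ in hands:
        target = "RMC" if hand == "left" else "LMC"
        scale = base
        if bilateral and is_in_phase(condition) and target == "RMC":
            scale = base * ip_nondominant_scale
        for k, r in enumerate(regions):
            if r == target:
                amp[k] = scale
    return amp


def region_coupling(
    region: str,
    strength: float,
    n_channels: int = 30,
    channel_regions: list[str] | None = None,
) -> np.ndarray:
    """Symmetric coupling matrix with ``strength`` between all channel pairs
    of one region and zero elsewhere."""
    regions = channel_regions or default_channel_regions(n_channels)
    idx = np.array([k for k, r in enumerate(regions) if r == region])
    if idx.size == 0:
        raise ValueError(f"no channels in region {region}")
    m = np.zeros((len(regions), len(regions)))
    m[np.ix_(idx, idx)] = strength
    np.fill_diagonal(m, 0.0)
    return m


def default_effect_spec(
    design: CohortDesign | None = None,
    n_channels: int = 30,
    amplitude: float = 0.5,
    radius_noise_sd: float = 0.05,
    radius_bias: float = 0.0,
    angvel_noise_sd: float = 0.1,
    left_hand_noise_scale: float = 1.4,
    rpfc_coupling_ip: float = 0.8,
    rpfc_coupling_ap: float = 0.3,
    **nirs_kwargs,
) -> dict[str, tuple[TrajectoryGroundTruth, NirsGroundTruth]]:
    """Effect spec emulating the study's qualitative findings.

    Contralateral activation amplitudes; larger trajectory noise for the
    non-dominant (left) hand in unilateral conditions; stronger right-
    prefrontal low-frequency coupling during in-phase than anti-phase
    bilateral movement.  Extra keyword arguments flow into every condition's
    :class:`NirsGroundTruth`.
    """
    conditions = design.conditions if design is not None else CONDITIONS
    regions = default_channel_regions(n_channels)
    spec = {}
    for cond in conditions:
        hands = condition_hands(cond)
        noise = radius_noise_sd
        if len(hands) == 1 and hands[0][0] == "left":
            noise = radius_noise_sd * left_hand_noise_scale
        tgt = TrajectoryGroundTruth(
            radius_bias=radius_bias,
            radius_noise_sd=noise,
            angvel_noise_sd=angvel_noise_sd,
            direction=hands[0][1],
        )
        coupling = np.zeros((n_channels, n_channels))
        if len(hands) == 2:
            kappa = rpfc_coupling_ip if is_in_phase(cond) else rpfc_coupling_ap
            coupling = region_coupling("RPFC", kappa, n_channels, regions)
        ngt = NirsGroundTruth(
            n_channels=n_channels,
            activation_amplitude=contralateral_amplitudes(cond, amplitude, n_channels, regions),
            coupling=coupling,
            **nirs_kwargs,
        )
        spec[cond] = (tgt, ngt)
    return spec


def gen_cohort(
    design: CohortDesign,
    effect_spec: dict[str, tuple[TrajectoryGroundTruth, NirsGroundTruth]],
    seed: int | None = None,
    subject_jitter_frac: float = 0.1,
    bias_subject_sd: float = 0.0,
    activation_bias_coupling: float = 0.0,
    left_hand_noise_scale: float = 1.0,
) -> Cohort:
    """Generate a full cohort of per-subject trajectories and recordings.

    ``effect_spec`` maps every condition of the design to its
    (TrajectoryGroundTruth, NirsGroundTruth) pair; activation amplitudes and
    condition-specific coupling are taken per condition, the physiological /
    noise / artifact parameters from the first condition's entry.

    Subject heterogeneity: each subject draws a latent standard-normal
    ``z``; the radius bias is shifted by ``bias_subject_sd * z`` and the
    activation amplitudes are scaled by ``(1 - activation_bias_coupling * z)``
    — a positive coupling therefore injects a negative dependence between
    activation and radius error.  All other scalar effects get independent
    multiplicative Gaussian jitter of relative size ``subject_jitter_frac``.

    Returns the cohort plus a tidy per-subject x condition ground-truth table
    for recovery tests.
    """
    missing = [c for c in design.conditions if c not in effect_spec]
    if missing:
        raise ValueError(f"effect_spec missing conditions: {missing}")
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    subject_seeds = root.spawn(max(design.n_subjects, 1))

    subjects: list[SubjectData] = []
    gt_rows: list[dict] = []
    for s in range(design.n_subjects):
        ss = subject_seeds[s]
        rng = np.random.default_rng(ss)
        z = rng.standard_normal()

        amp_by_cond: dict[str, np.ndarray] = {}
        coupling_by_cond: dict[str, np.ndarray] = {}
        traj_by_cond: dict[str, TrajectoryGroundTruth] = {}
        for cond in design.conditions:
            tgt, ngt = effect_spec[cond]
            jit = 1.0 + subject_jitter_frac * rng.standard_normal()
            bias = tgt.radius_bias + bias_subject_sd * z
            traj_by_cond[cond] = TrajectoryGroundTruth(
                guide_radius=tgt.guide_radius,
                guide_angular_velocity=tgt.guide_angular_velocity,
                radius_bias=bias,
                radius_noise_sd=max(tgt.radius_noise_sd * jit, 0.0),
                angvel_noise_sd=tgt.angvel_noise_sd,
                direction=tgt.direction,
            )
            amp_scale = (1.0 - activation_bias_coupling * z) * (
                1.0 + subject_jitter_frac * rng.standard_normal()
            )
            amp_by_cond[cond] = ngt.amplitude_for(cond) * amp_scale
            coupling_by_cond[cond] = ngt.coupling_for(cond)
            gt_rows.append(
                dict(subject=s, condition=cond, radius_bias=bias,
                     radius_noise_sd=traj_by_cond[cond].radius_noise_sd,
                     amp_scale=amp_scale, mean_amplitude=float(amp_by_cond[cond].mean()),
                     z=z)
            )

        base = effect_spec[design.conditions[0]][1]
        subject_gt = NirsGroundTruth(
            n_channels=base.n_channels,
            activation_amplitude=amp_by_cond,
            coupling=coupling_by_cond,
            cardiac_freq_hz=base.cardiac_freq_hz,
            resp_freq_hz=base.resp_freq_hz,
            mayer_freq_hz=base.mayer_freq_hz,
            cardiac_amp=base.cardiac_amp,
            resp_amp=base.resp_amp,
            mayer_amp=base.mayer_amp,
            lf_freq_hz=base.lf_freq_hz,
            lf_amp=base.lf_amp,
            phase_jitter=base.phase_jitter,
            artifact_rate=base.artifact_rate,
            artifact_amp=base.artifact_amp,
            noise_sd=base.noise_sd,
            hbr_ratio=base.hbr_ratio,
        )

        rec_seed, *trial_seeds = ss.spawn(1 + design.n_blocks_per_condition * len(design.conditions) * 2)
        recording = gen_nirs_recording(design, subject_gt, rec_seed)

        trajectories: list[TrajectoryTrace] = []
        idx = 0
        for block in range(design.n_blocks_per_condition):
            for cond in design.conditions:
                for hand, direction in condition_hands(cond):
                    tgt_c = traj_by_cond[cond]
                    noise_scale = left_hand_noise_scale if hand == "left" else 1.0
                    hand_gt = TrajectoryGroundTruth(
                        guide_radius=tgt_c.guide_radius,
                        guide_angular_velocity=tgt_c.guide_angular_velocity,
                        radius_bias=tgt_c.radius_bias,
                        radius_noise_sd=tgt_c.radius_noise_sd * noise_scale,
                        angvel_noise_sd=tgt_c.angvel_noise_sd,
                        direction=direction,
                    )
                    trajectories.append(
                        gen_trajectory(
                            hand_gt,
                            design.task_duration_s,
                            design.traj_rate_hz,
                            seed=trial_seeds[idx],
                            hand=hand,
                            condition=cond,
                            subject=s,
                            trial=block,
                        )
                    )
                    idx += 1
        subjects.append(SubjectData(subject=s, trajectories=trajectories, recording=recording))

    columns = ["subject", "condition", "radius_bias", "radius_noise_sd",
               "amp_scale", "mean_amplitude", "z"]
    ground_truth = pd.DataFrame(gt_rows, columns=columns)
    return Cohort(design=design, subjects=subjects, ground_truth=ground_truth)
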