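"""In-memory containers for multichannel fNIRS recordings.

A :class:`NirsRecording` holds either raw optical-density changes per
wavelength (time x channel x wavelength) or hemoglobin concentration changes
(time x channel), together with the channel-to-region map and the task block
timing.  :class:`HemoglobinSeries` is the converted/cleaned representation
consumed by the GLM and connectivity stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six cortical regions covered by the 30-channel montage.
REGIONS = ("LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL")

SIGNAL_KINDS = ("optical_density", "concentration")


def default_channel_regions(n_channels: int = 30) -> list[str]:
    """Default montage: channels split as evenly as possible over the six
    regions, in REGIONS order (channels 0-4 LPFC, 5-9 RPFC, ... 25-29 ROL
    for the standard 30-channel layout)."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    chunks = np.array_split(np.arange(n_channels), len(REGIONS))
    return [REGIONS[i] for i, chunk in enumerate(chunks) for _ in chunk]


@dataclass(frozen=True)
class Event:
    """One task block: onset and duration in seconds plus condition code."""

    onset: float
    duration: float
    condition: str

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.onset < 0:
            raise ValueError("event onset must be non-negative")


@dataclass
class NirsRecording:
    t: np.ndarray                      # seconds, uniform
    channels: np.ndarray               # (n, n_ch) concentration or (n, n_ch, n_wl) OD
    signal_kind: str                   # "optical_density" | "concentration"
    channel_regions: list[str]
    events: list[Event]
    rate: float                        # Hz
    wavelengths: tuple[float, ...] | None = None   # nm, required for optical_density
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        expected_ndim = 3 if self.signal_kind == "optical_density" else 2
        if self.channels.ndim != expected_ndim:
            raise ValueError(
                f"{self.signal_kind} data must be {expected_ndim}-d, got {self.channels.ndim}-d"
            )
        if self.signal_kind == "optical_density":
            if self.wavelengths is None or len(self.wavelengths) < 2:
                raise ValueError("optical_density recordings need >= 2 wavelengths")
            if self.channels.shape[2] != len(self.wavelengths):
                raise ValueError("last axis of channels must match number of wavelengths")
        if self.channels.shape[0] != self.t.shape[0]:
            raise ValueError("time axis of channels must match t")
        if len(self.channel_regions) != self.n_channels:
            raise ValueError(
                f"{self.n_channels} channels but {len(self.channel_regions)} region labels"
            )
        unknown = set(self.channel_regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if dt.min() <= 0:
                raise ValueError("t must be strictly increasing")
            if dt.max() - dt.min() > 0.01 * dt.mean():
                raise ValueError("t must be uniform within 1% jitter")
        end = self.t[-1] if self.t.size else 0.0
        for ev in self.events:
            if ev.onset + ev.duration > end + 1.0 / self.rate:
                raise ValueError(f"event {ev} extends past the end of the recording")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.condition, None)
        return list(seen)


@dataclass
class HemoglobinSeries:
    """Oxy-/deoxyhemoglobin concentration changes (micromolar) per channel."""

    t: np.ndarray
    dhbo: np.ndarray                   # (n, n_ch)
    dhbr: np.ndarray                   # (n, n_ch)
    rate: float
    channel_regions: list[str]
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.dhbo = np.asarray(self.dhbo, dtype=float)
        self.dhbr = np.asarray(self.dhbr, dtype=float)
        if self.dhbo.shape != self.dhbr.shape:
            raise ValueError("dhbo and dhbr must have identical shape")
        if self.dhbo.ndim != 2 or self.dhbo.shape[0] != self.t.shape[0]:
            raise ValueError("hemoglobin series must be (n_samples, n_channels)")
        if len(self.channel_regions) != self.dhbo.shape[1]:
            raise ValueError("channel_regions length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.dhbo.shape[1]

    def copy(self) -> "HemoglobinSeries":
        return HemoglobinSeries(
            t=self.t.copy(),
            dhbo=self.dhbo.copy(),
            dhbr=self.dhbr.copy(),
            rate=self.rate,
            channel_regions=list(self.channel_regions),
            events=list(self.events),
            meta=dict(self.meta),
        )
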