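"""Preprocessing: Beer-Lambert inversion, artifact detection/repair, filters."""

import numpy as np
import pytest

from nirsmoco.preprocess import (
    apply_filters,
    beer_lambert,
    beer_lambert_forward,
    detect_artifacts,
    moving_std,
    repair_spline,
)
from nirsmoco.recording import HemoglobinSeries, NirsRecording

WLS = (740.0, 808.0, 850.0)


def _od_recording(dhbo, dhbr, rate=11.0):
    od = beer_lambert_forward(dhbo, dhbr, WLS)
    n, n_ch = dhbo.shape
    regions = ["LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL"][:n_ch]
    return NirsRecording(t=np.arange(n) / rate, channels=od, signal_kind="optical_density",
                         channel_regions=regions, events=[], rate=rate, wavelengths=WLS)


def _hemo(data, rate=11.0, dhbr=None):
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape[0] == 1:
        data = data.T
    regions = ["LPFC"] * data.shape[1]
    return HemoglobinSeries(t=np.arange(data.shape[0]) / rate, dhbo=data,
                            dhbr=np.zeros_like(data) if dhbr is None else dhbr,
                            rate=rate, channel_regions=regions)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentrations(self):
        rec = _od_recording(np.zeros((20, 2)), np.zeros((20, 2)))
        h = beer_lambert(rec)
        assert np.all(h.dhbo == 0) and np.all(h.dhbr == 0)

    def test_forward_inverse_round_trip(self, rng):
        dhbo = rng.normal(0, 1, (50, 3))
        dhbr = rng.normal(0, 1, (50, 3))
        h = beer_lambert(_od_recording(dhbo, dhbr))
        assert np.abs(h.dhbo - dhbo).max() < 1e-10
        assert np.abs(h.dhbr - dhbr).max() < 1e-10

    def test_linearity(self, rng):
        dhbo = rng.normal(0, 1, (30, 2))
        dhbr = rng.normal(0, 1, (30, 2))
        rec1 = _od_recording(dhbo, dhbr)
        rec2 = _od_recording(2 * dhbo, 2 * dhbr)
        h1, h2 = beer_lambert(rec1), beer_lambert(rec2)
        assert np.allclose(h2.dhbo, 2 * h1.dhbo, atol=1e-12)
        assert np.allclose(h2.dhbr, 2 * h1.dhbr, atol=1e-12)

    def test_duplicate_wavelengths_rejected(self, rng):
        dhbo = rng.normal(0, 1, (20, 1))
        od = beer_lambert_forward(dhbo, dhbo, WLS)
        rec = NirsRecording(t=np.arange(20) / 11, channels=od[..., [0, 0, 0]],
                            signal_kind="optical_density", channel_regions=["LPFC"],
                            events=[], rate=11.0, wavelengths=(740.0, 740.0, 740.0))
        with pytest.raises(ValueError, match="wavelength"):
            beer_lambert(rec)


class TestArtifactDetection:
    def test_moving_std_matches_bruteforce(self, rng):
        x = rng.normal(0, 1, 200)
        window = 10
        ours = moving_std(x, window)
        half_lo, half_hi = (window - 1) // 2, window // 2
        for i in range(len(x)):
            lo, hi = max(i - half_lo, 0), min(i + half_hi + 1, len(x))
            assert ours[i] == pytest.approx(np.std(x[lo:hi], ddof=1), abs=1e-10)

    def test_constant_series_unflagged(self):
        h = _hemo(np.full(100, 3.0))
        assert not detect_artifacts(h).any_flagged

    def test_step_is_flagged_around_jump(self):
        x = np.zeros(300)
        x[150:] = 100.0
        mask = detect_artifacts(_hemo(x), threshold=5.0)
        assert mask.flagged[150, 0]
        segs = mask.segments[0]
        assert len(segs) == 1
        a, b = segs[0]
        assert a <= 150 < b

    def test_threshold_is_strict_inequality(self):
        # max moving std exactly at threshold -> not flagged
        x = np.zeros(100)
        x[50] = 10.0
        h = _hemo(x)
        peak = moving_std(x, 10).max()
        assert not detect_artifacts(h, threshold=peak).any_flagged
        assert detect_artifacts(h, threshold=peak * 0.999).any_flagged

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError):
            detect_artifacts(_hemo(np.zeros(5)), window=10)


class TestSplineRepair:
    def test_empty_mask_is_identity(self, rng):
        h = _hemo(rng.normal(0, 1, 100))
        mask = detect_artifacts(h, threshold=np.inf)
        out = repair_spline(h, mask)
        assert np.array_equal(out.dhbo, h.dhbo)

    def test_unflagged_samples_bit_identical(self, rng):
        x = rng.normal(0, 0.1, 200)
        x[100] += 50
        h = _hemo(x)
        mask = detect_artifacts(h, threshold=5.0, pad_s=0.2)
        out = repair_spline(h, mask)
        clean = ~mask.flagged[:, 0]
        assert np.array_equal(out.dhbo[clean, 0], h.dhbo[clean, 0])

    def test_spike_on_ramp_restored_to_ramp(self):
        x = np.linspace(0, 10, 200).copy()
        spike = x.copy()
        spike[100] += 100
        h = _hemo(spike)
        mask = detect_artifacts(h, threshold=5.0, pad_s=0.0)
        out = repair_spline(h, mask)
        assert np.abs(out.dhbo[:, 0] - x).max() < 1e-9

    def test_spike_on_sinusoid_within_neighbor_envelope(self):
        t = np.arange(400) / 11.0
        x = np.sin(2 * np.pi * 0.05 * t)
        spike = x.copy()
        spike[200] += 100
        h = _hemo(spike)
        mask = detect_artifacts(h, threshold=5.0, pad_s=0.0)
        out = repair_spline(h, mask)
        bad = np.flatnonzero(mask.flagged[:, 0])
        clean_idx = np.flatnonzero(~mask.flagged[:, 0])
        for i in bad:
            left = clean_idx[clean_idx < i][-2:]
            right = clean_idx[clean_idx > i][:2]
            nearest = np.concatenate([left, right])
            lo, hi = x[nearest].min(), x[nearest].max()
            margin = 0.1 * (hi - lo) + 1e-9
            assert lo - margin <= out.dhbo[i, 0] <= hi + margin

    def test_idempotence(self, rng):
        x = rng.normal(0, 0.1, 300)
        x[150:152] += 30
        h = _hemo(x)
        mask = detect_artifacts(h, threshold=3.0)
        once = repair_spline(h, mask)
        twice = repair_spline(once, mask)
        assert np.array_equal(once.dhbo, twice.dhbo)

    def test_boundary_artifact_extends_nearest_value(self):
        x = np.zeros(120)
        x[:3] = 60.0
        h = _hemo(x)
        mask = detect_artifacts(h, threshold=5.0)
        out = repair_spline(h, mask)
        assert np.isfinite(out.dhbo).all()
        assert np.abs(out.dhbo[0, 0]) < 1.0  # replaced, not left at 60


def _probe_gain(freq, rate=11.0, n_s=1200.0, **kw):
    t = np.arange(0, n_s, 1 / rate)
    x = np.sin(2 * np.pi * freq * t)
    h = _hemo(x, rate=rate)
    y = apply_filters(h, **kw).dhbo[:, 0]
    sl = slice(len(t) // 4, 3 * len(t) // 4)  # ignore transients
    return np.sqrt(np.mean(y[sl] ** 2)) / np.sqrt(np.mean(x[sl] ** 2))


class TestFilters:
    def test_passband_tone_preserved(self):
        assert _probe_gain(0.05) == pytest.approx(1.0, abs=0.05)

    def test_cardiac_tone_attenuated_20db(self):
        assert _probe_gain(1.0) < 10 ** (-20 / 20)

    def test_mayer_tone_attenuated_20db(self):
        assert _probe_gain(0.10) < 10 ** (-20 / 20)

    def test_linearity(self, rng):
        x = rng.normal(0, 1, (800, 2))
        y = rng.normal(0, 1, (800, 2))
        fa = apply_filters(_hemo(3 * x + 2 * y)).dhbo
        fb = 3 * apply_filters(_hemo(x)).dhbo + 2 * apply_filters(_hemo(y)).dhbo
        assert np.abs(fa - fb).max() < 1e-9

    def test_band_edges_validated(self):
        h = _hemo(np.zeros(100))
        with pytest.raises(ValueError):
            apply_filters(h, bandpass=(0.021, 6.0))  # above Nyquist at 11 Hz
        with pytest.raises(ValueError):
            apply_filters(h, bandpass=(0.0, 0.6))


class TestEndToEndAttenuation:
    def test_physiological_nuisance_removed_task_band_kept(self):
        """Cardiac and Mayer components lose >= 90% power; the slow task-band
        component keeps >= 80%.  (The 0.25 Hz respiratory component lies
        inside the pass band by design and is not attenuated.)"""
        rate = 11.0
        t = np.arange(0, 1500, 1 / rate)
        sl = slice(len(t) // 4, 3 * len(t) // 4)

        def power_ratio(freq):
            x = np.sin(2 * np.pi * freq * t)
            y = apply_filters(_hemo(x, rate=rate)).dhbo[:, 0]
            return np.mean(y[sl] ** 2) / np.mean(x[sl] ** 2)

        assert power_ratio(1.0) < 0.10      # cardiac
        assert power_ratio(0.1) < 0.10      # Mayer
        assert power_ratio(0.05) > 0.80     # hemodynamic task band
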