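"""Filtering, blink correction, epoching and artifact criteria."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vac
from vac.errors import EmptyInputError, EmptyResultError, ParameterError
from vac.preprocess import EpochSet, flag_artifacts

from conftest import make_recording, sine

FS = 256.0


def steady_state_gain(freq: float, n_sec: float = 8.0) -> float:
    """Measured steady-state amplitude of a unit sinusoid after filtering."""
    n = int(n_sec * FS)
    rec = make_recording({"Fz": sine(freq, n)})
    out = vac.bandpass_filter(rec)
    tail = out.channel("Fz")[n // 2:]
    return float(np.abs(tail).max())


class TestBandpass:
    def test_dc_offset_decays(self):
        rec = make_recording({"Fz": np.full(2048, 50.0)})
        out = vac.bandpass_filter(rec)
        assert np.abs(out.channel("Fz")[-256:]).max() < 1.0

    def test_passband_10hz_near_unity(self):
        # analytic magnitude of the band-pass at 10 Hz is ~1
        assert steady_state_gain(10.0) == pytest.approx(1.0, abs=0.05)

    def test_stopband_50hz_attenuated(self):
        # 5th-order low edge at 30 Hz: (50/30)^5 ≈ 13x attenuation
        assert steady_state_gain(50.0) <= 0.1

    def test_high_edge_above_nyquist_rejected(self):
        rec = make_recording({"Fz": np.zeros(512)})
        with pytest.raises(ParameterError):
            vac.bandpass_filter(rec, low=1, high=130)

    def test_linearity(self, rng):
        x = rng.normal(0, 10, 1024)
        y = rng.normal(0, 10, 1024)
        fx = vac.bandpass_filter(make_recording({"Fz": x})).data
        fy = vac.bandpass_filter(make_recording({"Fz": y})).data
        fxy = vac.bandpass_filter(make_recording({"Fz": 2 * x + 3 * y})).data
        assert np.allclose(fxy, 2 * fx + 3 * fy, atol=1e-9)


def _blinky_record(rng, blink_times=(2.0, 5.0, 8.0), amp=150.0, mix=0.6,
                   duration=12.0, background=5.0):
    n = int(duration * FS)
    fpz = background * rng.standard_normal(n)
    af3 = background * rng.standard_normal(n)
    n_b = int(0.3 * FS)
    wave = amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_b) / (n_b - 1)))
    for t0 in blink_times:
        s = int(t0 * FS)
        fpz[s:s + n_b] += wave
        af3[s:s + n_b] += mix * wave
    return make_recording({"Fpz": fpz, "AF3": af3}), blink_times


class TestBlinks:
    def test_injected_blinks_found(self, rng):
        rec, times = _blinky_record(rng)
        filt = vac.bandpass_filter(rec)
        ann = vac.detect_blinks(filt)
        assert len(ann) == 3
        for (a, b), t0 in zip(ann.intervals, times):
            assert a <= t0 + 0.05 and b >= t0 + 0.25  # covers injection ±50 ms

    def test_blink_free_record_empty(self, rng):
        rec, _ = _blinky_record(rng, blink_times=())
        ann = vac.detect_blinks(vac.bandpass_filter(rec))
        assert len(ann) == 0

    def test_oscillation_does_not_trigger(self):
        # sustained 20 μV alpha is not blink-like
        n = int(12 * FS)
        rec = make_recording({"Fpz": sine(10.0, n, amp=20.0)})
        ann = vac.detect_blinks(rec)
        assert len(ann) == 0

    def test_removal_reduces_propagated_blink(self, rng):
        rec, times = _blinky_record(rng, mix=0.6)
        filt = vac.bandpass_filter(rec)
        ann = vac.detect_blinks(filt)
        clean = vac.remove_blinks(filt, ann)
        # residual on AF3 during blinks <= 10% of the propagated amplitude
        mask = np.zeros(rec.n_samples, bool)
        for t0 in times:
            mask[int(t0 * FS):int((t0 + 0.3) * FS)] = True
        resid = np.abs(clean.channel("AF3")[mask]).max()
        assert resid <= 0.1 * 0.6 * 150 + 3 * 5.0  # mixing residual + noise

    def test_no_blink_is_identity(self, rng):
        rec, _ = _blinky_record(rng, blink_times=())
        filt = vac.bandpass_filter(rec)
        ann = vac.detect_blinks(filt)
        out = vac.remove_blinks(filt, ann)
        assert out is filt  # bit-identical pass-through

    def test_outside_intervals_untouched(self, rng):
        rec, times = _blinky_record(rng)
        filt = vac.bandpass_filter(rec)
        ann = vac.detect_blinks(filt)
        out = vac.remove_blinks(filt, ann)
        mask = np.ones(rec.n_samples, bool)
        for a, b in ann.intervals:
            mask[int(a * FS):int(b * FS) + 2] = False
        assert np.array_equal(out.channel("AF3")[mask],
                              filt.channel("AF3")[mask])


class TestEpoching:
    def test_count_900s(self, rng):
        rec = make_recording({"Fz": rng.normal(0, 5, int(900 * FS))})
        assert len(vac.make_epochs(rec, 2.0, 0.125)) == 7185

    def test_single_epoch(self, rng):
        rec = make_recording({"Fz": rng.normal(0, 5, 512)})
        assert len(vac.make_epochs(rec, 2.0, 0.125)) == 1

    def test_too_short(self, rng):
        rec = make_recording({"Fz": rng.normal(0, 5, 486)})  # 1.9 s
        with pytest.raises(EmptyInputError):
            vac.make_epochs(rec, 2.0, 0.125)

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(min_value=512, max_value=8192))
    def test_count_matches_closed_form(self, n):
        rec = make_recording({"Fz": np.zeros(n)})
        eps = vac.make_epochs(rec, 2.0, 0.125)
        assert len(eps) == (n - 512) // 32 + 1
        # start grid is exactly 0, step, 2·step, ...
        assert np.allclose(np.diff(eps.starts), 0.125)


def _one_epoch(samples: np.ndarray, fs: float = FS) -> EpochSet:
    return EpochSet(starts=np.array([0.0]),
                    data=samples[None, None, :].astype(float),
                    channel_names=["Fz"], fs=fs, epoch_length=len(samples) / fs,
                    step=0.125)


class TestArtifactCriteria:
    def test_threshold_spike(self):
        x = np.zeros(512)
        x[100] = 120.0
        eps = flag_artifacts(_one_epoch(x))
        assert "threshold" in eps.flags[0]

    def test_trend_ramp(self):
        # clean linear ramp 0→40 μV over 2 s: slope 20 μV/s, R² = 1
        x = np.linspace(0.0, 40.0, 512)
        eps = flag_artifacts(_one_epoch(x))
        assert eps.flags[0] == {"trend"}

    def test_clean_sinusoid(self):
        # 20 μV 10 Hz: max consecutive diff = 2π·10·20/256 ≈ 4.9 μV < 25
        eps = flag_artifacts(_one_epoch(sine(10.0, 512, amp=20.0)))
        assert eps.flags[0] == frozenset()

    def test_jump(self):
        x = np.zeros(512)
        x[200:] = 30.0  # one 30 μV step
        eps = flag_artifacts(_one_epoch(x))
        assert "jump" in eps.flags[0]

    def test_idempotent_and_additive(self):
        x = np.zeros(512)
        x[100] = 120.0
        once = flag_artifacts(_one_epoch(x))
        twice = flag_artifacts(once)
        assert once.flags == twice.flags

    def test_blink_channel_excluded(self):
        data = np.zeros((1, 2, 512))
        data[0, 0, 100] = 150.0  # huge excursion, but on Fpz
        eps = EpochSet(starts=np.array([0.0]), data=data,
                       channel_names=["Fpz", "Fz"], fs=FS,
                       epoch_length=2.0, step=0.125)
        assert flag_artifacts(eps).flags[0] == frozenset()


class TestDropArtifacts:
    def _epochs(self, n=10, bad=(1, 4, 7)):
        data = np.zeros((n, 1, 512))
        for i in bad:
            data[i, 0, 0] = 200.0
        eps = EpochSet(starts=np.arange(n) * 0.125, data=data,
                       channel_names=["Fz"], fs=FS, epoch_length=2.0,
                       step=0.125)
        return flag_artifacts(eps)

    def test_drop_preserves_times(self):
        eps = self._epochs()
        kept = vac.drop_artifacts(eps)
        assert len(kept) == 7
        assert np.allclose(kept.starts,
                           [0.0, 0.25, 0.375, 0.625, 0.75, 1.0, 1.125])

    def test_all_clean_identity(self):
        eps = self._epochs(bad=())
        assert len(vac.drop_artifacts(eps)) == 10

    def test_all_flagged_error_with_census(self):
        eps = self._epochs(n=3, bad=(0, 1, 2))
        with pytest.raises(EmptyResultError) as exc:
            vac.drop_artifacts(eps)
        assert exc.value.census["threshold"] == 3
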