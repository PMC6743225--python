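"""From raw EEG to clean, artifact-flagged epochs.

The chain is: causal band-pass filter (1–30 Hz Butterworth, 5th order) →
regression-based blink correction driven by the prefrontal Fpz channel →
overlapping 2-s epochs shifted by 0.125 s → three artifact criteria
(amplitude threshold ±100 μV, linear-trend R² > 0.3 with |slope| > 10 μV/s,
sample-to-sample jump > 25 μV) → removal of flagged epochs.

Blink correction follows the regression-with-gating principle: a robust
threshold on the filtered Fpz channel detects blink intervals, per-channel
regression coefficients are estimated on blink samples only, and the scaled
Fpz signal is subtracted *only inside* detected intervals — a blink-free
recording passes through bit-identical.  No EOG channel is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .errors import EmptyInputError, EmptyResultError, ParameterError
from .session_io import EEGRecording

ARTIFACT_FLAGS = ("threshold", "trend", "jump")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BlinkAnnotation:
    """Blink intervals on the blink channel plus per-channel regression βs."""

    intervals: list[tuple[float, float]]
    coefficients: dict[str, float] = field(default_factory=dict)
    channel: str = "Fpz"

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class EpochSet:
    """Overlapping fixed-length windows with per-epoch artifact flags.

    ``data`` is ``(n_epochs, n_channels, n_samples)``; ``starts`` the epoch
    onset times in seconds; ``flags`` one frozenset per epoch drawn from
    ``{"threshold", "trend", "jump"}`` — an epoch is clean iff its set is
    empty.
    """

    starts: np.ndarray
    data: np.ndarray
    channel_names: list[str]
    fs: float
    epoch_length: float
    step: float
    flags: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        if not self.flags:
            self.flags = [frozenset()] * len(self.starts)
        if len(self.flags) != len(self.starts):
            raise ParameterError("one flag set per epoch required")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def clean_mask(self) -> np.ndarray:
        return np.array([not f for f in self.flags], dtype=bool)

    def flag_census(self) -> dict[str, int]:
        census = {name: 0 for name in ARTIFACT_FLAGS}
        for f in self.flags:
            for name in f:
                census[name] += 1
        return census

    def subset(self, mask: np.ndarray) -> "EpochSet":
        idx = np.flatnonzero(mask)
        return EpochSet(self.starts[idx], self.data[idx], self.channel_names,
                        self.fs, self.epoch_length, self.step,
                        [self.flags[i] for i in idx])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass_filter(rec: EEGRecording, low: float = 1.0, high: float = 30.0,
                    order: int = 5, zero_phase: bool = False) -> EEGRecording:
    """Band-pass Butterworth filter applied per channel.

    Causal (forward-only) by default so the output at time t depends only on
    samples up to t; ``zero_phase=True`` switches to offline forward-backward
    filtering.
    """
    nyq = rec.fs / 2
    if not (0 < low < high):
        raise ParameterError("need 0 < low < high")
    if high >= nyq:
        raise ParameterError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    out = rec.copy()
    out.data = np.ascontiguousarray(filt(sos, rec.data, axis=1))
    return out


# ---------------------------------------------------------------------------
# blink handling
# ---------------------------------------------------------------------------

def detect_blinks(rec: EEGRecording, blink_channel: str = "Fpz",
                  mad_mult: float = 4.0, min_dur_s: float = 0.05,
                  pad_s: float = 0.05, stat_window_s: float = 30.0,
                  merge_gap_s: float = 0.2) -> BlinkAnnotation:
    """Detect blink intervals on the (already filtered) blink channel.

    A sample is blink-candidate when |Fpz| exceeds median + ``mad_mult`` ×
    MAD of |Fpz|.  The robust statistics come from the leading
    ``stat_window_s`` seconds only, so truncating the future never changes
    past detections (the chain runs online).  Candidate runs shorter than
    ``min_dur_s`` are discarded; surviving runs are padded by ``pad_s`` on
    each side, and intervals separated by less than ``merge_gap_s`` merge —
    the band-pass filter rings after each blink, and one blink must map to
    one interval.
    """
    x = rec.channel(blink_channel)
    absx = np.abs(x)
    n_stat = min(len(absx), max(1, int(round(stat_window_s * rec.fs))))
    med = np.median(absx[:n_stat])
    mad = np.median(np.abs(absx[:n_stat] - med))
    thr = med + mad_mult * max(mad, 1e-12)
    above = absx > thr

    min_run = max(1, int(round(min_dur_s * rec.fs)))
    intervals: list[tuple[float, float]] = []
    run_starts: list[int] = []
    run_ends: list[int] = []
    idx = np.flatnonzero(above)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = [idx[0]] + list(idx[breaks + 1])
        run_ends = list(idx[breaks]) + [idx[-1]]
    t0 = rec.start_time
    for s, e in zip(run_starts, run_ends):
        if e - s + 1 < min_run:
            continue
        a = max(t0, t0 + s / rec.fs - pad_s)
        b = min(t0 + rec.duration, t0 + (e + 1) / rec.fs + pad_s)
        if intervals and a - intervals[-1][1] < merge_gap_s:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
        else:
            intervals.append((a, b))

    coeffs = _fit_blink_coefficients(rec, intervals, blink_channel)
    return BlinkAnnotation(intervals, coeffs, blink_channel)


def _interval_mask(rec: EEGRecording, intervals) -> np.ndarray:
    mask = np.zeros(rec.n_samples, dtype=bool)
    for a, b in intervals:
        i = max(0, int(np.ceil((a - rec.start_time) * rec.fs)))
        j = min(rec.n_samples, int(np.floor((b - rec.start_time) * rec.fs)) + 1)
        mask[i:j] = True
    return mask


def _fit_blink_coefficients(rec: EEGRecording, intervals,
                            blink_channel: str) -> dict[str, float]:
    """Least-squares β per channel, estimated on blink samples only."""
    if not intervals:
        return {}
    mask = _interval_mask(rec, intervals)
    ref = rec.channel(blink_channel)[mask]
    denom = float(ref @ ref)
    if denom <= 0:
        return {}
    coeffs = {}
    for name in rec.channel_names:
        if name == blink_channel:
            continue
        coeffs[name] = float(rec.channel(name)[mask] @ ref) / denom
    return coeffs


def remove_blinks(rec: EEGRecording, ann: BlinkAnnotation) -> EEGRecording:
    """Subtract β·Fpz inside blink intervals; outside them, pass through.

    The regression coefficients are cumulative-causal: the correction of
    each interval uses β fitted on the blink samples observed up to and
    including that interval, so past output never depends on future data.
    With an empty annotation the input is returned unchanged (same object),
    honouring the no-blink/no-effect contract.
    """
    if not ann.intervals:
        return rec
    out = rec.copy()
    ref = rec.channel(ann.channel)
    rows = [out.channel_index(n) for n in rec.channel_names
            if n != ann.channel]
    sum_rr = 0.0
    sum_rx = np.zeros(len(rows))
    for a, b in ann.intervals:
        i = max(0, int(np.ceil((a - rec.start_time) * rec.fs)))
        j = min(rec.n_samples, int(np.floor((b - rec.start_time) * rec.fs)) + 1)
        if j <= i:
            continue
        r = ref[i:j]
        sum_rr += float(r @ r)
        sum_rx += rec.data[rows, i:j] @ r
        if sum_rr <= 0:
            continue
        beta = sum_rx / sum_rr
        out.data[rows, i:j] = rec.data[rows, i:j] - beta[:, None] * r
    return out


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def make_epochs(rec: EEGRecording, length: float = 2.0,
                step: float = 0.125) -> EpochSet:
    """Cut overlapping epochs: starts 0, step, 2·step, … while they fit.

    The epoch count equals ``floor((T − length)/step) + 1`` for a recording
    of duration T.
    """
    if length <= 0 or step <= 0:
        raise ParameterError("epoch length and step must be positive")
    n_len = int(round(length * rec.fs))
    n_step = int(round(step * rec.fs))
    if n_step < 1:
        raise ParameterError("epoch step below one sample")
    if rec.n_samples < n_len:
        raise EmptyInputError(
            f"recording of {rec.duration:.3f} s shorter than epoch length {length} s")
    n_epochs = (rec.n_samples - n_len) // n_step + 1
    # strided view over overlapping windows, copied once as float32: epochs
    # overlap 16x at the default grid, so a compact dtype keeps a 15-min
    # session's epoch block in the hundreds of MB instead of GBs
    view = np.lib.stride_tricks.sliding_window_view(rec.data, n_len, axis=1)
    data = view[:, ::n_step, :][:, :n_epochs].transpose(1, 0, 2).astype(np.float32)
    starts = rec.start_time + np.arange(n_epochs) * n_step / rec.fs
    return EpochSet(starts, data, list(rec.channel_names), rec.fs, length, step)


# ---------------------------------------------------------------------------
# artifact criteria
# ---------------------------------------------------------------------------

def flag_artifacts(epochs: EpochSet, amp_limit: float = 100.0,
                   trend_r2: float = 0.3, trend_slope: float = 10.0,
                   jump_limit: float = 25.0,
                   exclude_channels: tuple[str, ...] = ("Fpz",)) -> EpochSet:
    """Annotate each epoch with the subset of artifact criteria it violates.

    All three criteria are evaluated per channel and OR-ed across channels.
    The blink channel is excluded by default: it exists solely for ocular
    artifact handling and is not part of the analyzed data.  Flags are
    additive — existing flags are never removed.
    """
    if len(epochs) == 0:
        raise EmptyInputError("no epochs to flag")
    keep = [i for i, n in enumerate(epochs.channel_names)
            if n not in exclude_channels]
    x = epochs.data[:, keep, :]  # (n_ep, n_ch, n_s)
    n_ep, n_ch, n_s = x.shape

    amp_bad = np.abs(x).max(axis=2) > amp_limit

    if n_s > 1:
        d = np.abs(np.diff(x, axis=2))
        jump_bad = d.max(axis=2) > jump_limit
        del d
    else:
        jump_bad = np.zeros_like(amp_bad)

    # least-squares line per (epoch, channel): slope in μV/s and R²
    t = (np.arange(n_s) / epochs.fs).astype(x.dtype)
    tc = t - t.mean()
    stt = float(tc @ tc)
    xm = x.mean(axis=2, dtype=np.float64)
    sxt = np.einsum("ecs,s->ec", x, tc, optimize=True)  # centering in t
    slope = sxt / stt
    ss_tot = np.einsum("ecs,ecs->ec", x, x) - n_s * xm ** 2
    ss_reg = sxt ** 2 / stt
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / np.maximum(ss_tot, 1e-300), 0.0)
    trend_bad = (r2 > trend_r2) & (np.abs(slope) > trend_slope)

    new_flags = []
    for i, old in enumerate(epochs.flags):
        f = set(old)
        if amp_bad[i].any():
            f.add("threshold")
        if trend_bad[i].any():
            f.add("trend")
        if jump_bad[i].any():
            f.add("jump")
        new_flags.append(frozenset(f))
    return EpochSet(epochs.starts, epochs.data, epochs.channel_names,
                    epochs.fs, epochs.epoch_length, epochs.step, new_flags)


def drop_artifacts(epochs: EpochSet) -> EpochSet:
    """Keep clean epochs only, preserving original start times."""
    mask = epochs.clean_mask
    if not mask.any():
        raise EmptyResultError("all epochs flagged as artifact",
                               epochs.flag_census())
    return epochs.subset(mask)


# ---------------------------------------------------------------------------
# convenience chain
# ---------------------------------------------------------------------------

def preprocess(rec: EEGRecording, cfg: PipelineConfig | None = None) -> EpochSet:
    """Full chain: filter → blink-correct → epoch → flag."""
    cfg = cfg or PipelineConfig()
    filt = bandpass_filter(rec, cfg.filter.low_hz, cfg.filter.high_hz,
                           cfg.filter.order, cfg.filter.zero_phase)
    if cfg.blink.channel in rec.channel_names:
        ann = detect_blinks(filt, cfg.blink.channel, cfg.blink.mad_mult,
                            cfg.blink.min_dur_s, cfg.blink.pad_s)
        filt = remove_blinks(filt, ann)
    epochs = make_epochs(filt, cfg.epoch.length_s, cfg.epoch.step_s)
    return flag_artifacts(epochs, cfg.artifact.amp_uv, cfg.artifact.trend_r2,
                          cfg.artifact.trend_slope_uv_s, cfg.artifact.jump_uv,
                          exclude_channels=(cfg.blink.channel,))
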