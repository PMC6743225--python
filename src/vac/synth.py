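"""Synthetic EEG, eyes-closed and gaze sessions with known ground truth.

The generator emulates the statistical structure the vigilance pipeline
exploits, without claiming physiological realism:

* every channel carries a pink-noise floor plus band-limited oscillations
  (band-pass filtered white noise, so PSDs are realistically broad);
* a latent piecewise-constant vigilance state modulates band power the way
  drowsiness does — in the Low state frontal theta power doubles, posterior
  alpha rises ×1.8 and frontal beta drops to ×0.7 of its High-state level
  (slow rhythms grow and fast rhythms shrink as vigilance falls);
* eye blinks are injected on Fpz as 300-ms raised-cosine deflections and
  mixed into the other frontal channels with fixed coefficients;
* gross artifacts (square-pulse excursions exceeding ±100 μV and
  electrode-pop steps with fast decay) corrupt a stated rate of epochs;
* gaze sessions alternate fixations and saccades at 60 Hz, with fixation
  durations drawn longer — hence fewer fixations per second — in the High
  state, and object onsets answered by a planted first look whose latency
  is drawn shorter in the High state (4 s vs 5 s on average).

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import CENTRO_PARIETAL, FRONTAL, MONTAGE, PARIETAL
from .errors import ParameterError
from .session_io import EEGRecording, GazeStream, ObjectEventTable, ObjectTrack

HIGH = "High"
LOW = "Low"


# ---------------------------------------------------------------------------
# latent state
# ---------------------------------------------------------------------------

@dataclass
class LatentTimeline:
    """Piecewise-constant vigilance state over the session; starts High."""

    boundaries: np.ndarray  # segment start times, boundaries[0] == 0
    states: list[str]       # one per segment
    duration: float

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if len(self.boundaries) != len(self.states) or len(self.states) == 0:
            raise ParameterError("one state per segment required")
        if self.boundaries[0] != 0.0:
            raise ParameterError("timeline must start at t=0")
        if self.states[0] != HIGH:
            raise ParameterError("timeline must start in the High state")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ParameterError("segment boundaries must increase")
        if self.boundaries[-1] >= self.duration:
            raise ParameterError("last segment must start before the end")
        bad = set(self.states) - {HIGH, LOW}
        if bad:
            raise ParameterError(f"unknown states {sorted(bad)}")

    @classmethod
    def from_segments(cls, segments: list[tuple[float, str]],
                      duration: float) -> "LatentTimeline":
        segments = sorted(segments)
        return cls(np.array([s for s, _ in segments]),
                   [st for _, st in segments], duration)

    @classmethod
    def calibration(cls, duration: float = 900.0) -> "LatentTimeline":
        """High first half, Low second half: the calibration-run shape."""
        return cls.from_segments([(0.0, HIGH), (duration / 2, LOW)], duration)

    def state_at(self, t: float) -> str:
        k = int(np.searchsorted(self.boundaries, t, side="right")) - 1
        return self.states[max(k, 0)]

    def high_mask(self, times: np.ndarray) -> np.ndarray:
        """True where the state at each time is High."""
        k = np.searchsorted(self.boundaries, np.asarray(times, dtype=float),
                            side="right") - 1
        st = np.array([s == HIGH for s in self.states])
        return st[np.maximum(k, 0)]

    def low_fraction(self, times: np.ndarray) -> float:
        m = self.high_mask(times)
        return float((~m).sum() / len(m)) if len(m) else float("nan")


# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

@dataclass
class EEGGenSpec:
    """Knobs of the EEG generator; defaults encode the study conditions."""

    fs: float = 256.0
    montage: tuple[str, ...] = MONTAGE
    iaf: float = 10.0
    pink_rms: float = 10.0       # μV, broadband 1/f floor on every channel
    theta_rms: float = 5.0       # μV, frontal theta oscillation (High state)
    alpha_rms: float = 8.0       # μV, centro-parietal alpha (High state)
    beta_rms: float = 4.0        # μV, frontal beta (High state)
    parietal_theta_rms: float = 4.0  # μV, unmodulated parietal theta
    low_theta_mult: float = 2.0  # power multipliers applied in the Low state
    low_alpha_mult: float = 1.8
    low_beta_mult: float = 0.7
    blink_rate_per_min: float = 8.0
    blink_amp_uv: float = 150.0
    blink_dur_s: float = 0.3
    blink_mix_af: float = 0.6    # propagation on to AF* channels
    blink_mix_f: float = 0.3     # ... and F*/Fz channels
    artifact_rate_per_min: float = 2.0
    seed: int = 0


@dataclass
class EEGGroundTruth:
    """Exact latent state, blink times and corrupted intervals."""

    timeline: LatentTimeline
    blink_intervals: list[tuple[float, float]]
    artifact_events: list[tuple[float, float, str]]  # (start, end, kind)

    def corrupted_epoch_mask(self, starts: np.ndarray,
                             epoch_length: float) -> np.ndarray:
        """Epochs overlapping any injected artifact event."""
        starts = np.asarray(starts, dtype=float)
        mask = np.zeros(len(starts), dtype=bool)
        for a, b, _ in self.artifact_events:
            mask |= (starts < b) & (starts + epoch_length > a)
        return mask

    def collar_epoch_mask(self, starts: np.ndarray, epoch_length: float,
                          pre: float = 0.5, post: float = 1.0) -> np.ndarray:
        """Epochs inside a scoring collar around events.

        The causal filter smears each event slightly beyond its injection
        window, so epochs that only touch the margin are scored neither as
        required detections nor as false alarms (a standard collar rule in
        event-detection scoring).
        """
        starts = np.asarray(starts, dtype=float)
        mask = np.zeros(len(starts), dtype=bool)
        for a, b, _ in self.artifact_events:
            mask |= (starts < b + post) & (starts + epoch_length > a - pre)
        return mask & ~self.corrupted_epoch_mask(starts, epoch_length)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                rms: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(f)
    nz = f > 0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float, rms: float) -> np.ndarray:
    """Band-pass filtered white noise scaled to a target RMS."""
    low = max(low, 0.1)
    high = min(high, fs / 2 - 1.0)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _state_gain(timeline: LatentTimeline, n: int, fs: float,
                mult: float) -> np.ndarray:
    """Per-sample amplitude gain: √mult inside Low segments, 1 in High."""
    t = np.arange(n) / fs
    g = np.where(timeline.high_mask(t), 1.0, math.sqrt(mult))
    return g


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   duration: float, margin: float,
                   min_gap: float) -> list[float]:
    if rate_per_min <= 0:
        return []
    n = rng.poisson(rate_per_min * duration / 60.0)
    times = np.sort(rng.uniform(margin, duration - margin, size=n))
    out: list[float] = []
    for t in times:
        if not out or t - out[-1] >= min_gap:
            out.append(float(t))
    return out


def simulate_eeg_session(spec: EEGGenSpec, timeline: LatentTimeline,
                         duration: float) -> tuple[EEGRecording, EEGGroundTruth]:
    """Generate a state-modulated EEG session with blinks and artifacts."""
    if duration < 60:
        raise ParameterError("session duration must be at least 60 s")
    if abs(timeline.duration - duration) > 1e-9:
        raise ParameterError("timeline duration must match the session")
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(duration * fs))
    names = list(spec.montage)
    data = np.zeros((len(names), n))

    iaf = spec.iaf
    theta_band = (iaf - 6, iaf - 2)
    alpha_band = (iaf - 2, iaf + 2)
    beta_band = (iaf + 2, iaf + 16)
    g_theta = _state_gain(timeline, n, fs, spec.low_theta_mult)
    g_alpha = _state_gain(timeline, n, fs, spec.low_alpha_mult)
    g_beta = _state_gain(timeline, n, fs, spec.low_beta_mult)

    for i, name in enumerate(names):
        x = _pink_noise(rng, n, fs, spec.pink_rms)
        if name in FRONTAL:
            x = x + g_theta * _band_noise(rng, n, fs, *theta_band, spec.theta_rms)
            x = x + g_beta * _band_noise(rng, n, fs, *beta_band, spec.beta_rms)
        if name in CENTRO_PARIETAL:
            x = x + g_alpha * _band_noise(rng, n, fs, *alpha_band, spec.alpha_rms)
        if name in PARIETAL:
            x = x + _band_noise(rng, n, fs, *theta_band, spec.parietal_theta_rms)
        data[i] = x

    # blinks: raised cosine on Fpz, mixed into AF*/F* rows
    blink_times = _poisson_times(rng, spec.blink_rate_per_min, duration,
                                 margin=1.0, min_gap=1.0)
    blink_intervals = []
    n_blink = int(round(spec.blink_dur_s * fs))
    wave = spec.blink_amp_uv * 0.5 * (1 - np.cos(
        2 * np.pi * np.arange(n_blink) / max(n_blink - 1, 1)))
    fpz = names.index("Fpz") if "Fpz" in names else None
    for t0 in blink_times:
        s = int(round(t0 * fs))
        e = min(s + n_blink, n)
        w = wave[:e - s]
        if fpz is not None:
            data[fpz, s:e] += w
            for i, name in enumerate(names):
                if name.startswith("AF"):
                    data[i, s:e] += spec.blink_mix_af * w
                elif name.startswith("F") and name != "Fpz":
                    data[i, s:e] += spec.blink_mix_f * w
        blink_intervals.append((t0, t0 + spec.blink_dur_s))

    # gross artifacts: square-pulse excursions and electrode-pop steps
    events = []
    art_times = _poisson_times(rng, spec.artifact_rate_per_min, duration,
                               margin=3.0, min_gap=6.0)
    non_blink_rows = [i for i, nm in enumerate(names) if nm != "Fpz"]
    for k, t0 in enumerate(art_times):
        row = int(rng.choice(non_blink_rows))
        s = int(round(t0 * fs))
        if k % 2 == 0:
            dur = float(rng.uniform(0.25, 0.6))
            e = min(s + int(round(dur * fs)), n)
            amp = float(rng.uniform(250, 400)) * (1 if rng.random() < 0.5 else -1)
            data[row, s:e] += amp
            events.append((t0, t0 + dur, "excursion"))
        else:
            tau = 0.4
            dur = 0.3
            e = min(s + int(round(3 * tau * fs)), n)
            tt = np.arange(e - s) / fs
            amp = float(rng.uniform(400, 600)) * (1 if rng.random() < 0.5 else -1)
            data[row, s:e] += amp * np.exp(-tt / tau)
            events.append((t0, t0 + dur, "pop"))

    rec = EEGRecording(names, data, fs=fs)
    gt = EEGGroundTruth(timeline=timeline, blink_intervals=blink_intervals,
                        artifact_events=events)
    return rec, gt


def simulate_eyes_closed(iaf: float, duration: float = 60.0,
                         seed: int = 0) -> EEGRecording:
    """Eyes-closed calibration segment with a parietal-dominant alpha peak."""
    if not (7.0 <= iaf <= 13.0):
        raise ParameterError(f"iaf {iaf} Hz outside the supported 7-13 Hz range")
    rng = np.random.default_rng(seed)
    fs = 256.0
    n = int(round(duration * fs))
    names = list(MONTAGE)
    data = np.zeros((len(names), n))
    for i, name in enumerate(names):
        x = _pink_noise(rng, n, fs, 8.0)
        if name in PARIETAL:
            x = x + _band_noise(rng, n, fs, iaf - 0.4, iaf + 0.4, 12.0)
        elif name in CENTRO_PARIETAL:
            x = x + _band_noise(rng, n, fs, iaf - 0.4, iaf + 0.4, 5.0)
        data[i] = x
    return EEGRecording(names, data, fs=fs)


# ---------------------------------------------------------------------------
# gaze generation
# ---------------------------------------------------------------------------

@dataclass
class GazeGenSpec:
    rate: float = 60.0
    #: mean fixation durations per state (s), derived from the target
    #: fixation rates: with a 2-sample saccade between fixations the cycle
    #: is (n_fix + 2) samples, so 4.3 fix/s (High) and 4.6 fix/s (Low) at
    #: 60 Hz need mean spans of (60/4.3 − 3)/60 and (60/4.6 − 3)/60 s;
    #: vigilant operators fixate longer, hence fewer fixations per second
    fix_dur_high_s: float = 0.183
    fix_dur_low_s: float = 0.167
    #: planted first-look latency per state (s)
    look_latency_high_s: float = 4.0
    look_latency_low_s: float = 5.0
    look_latency_sd_s: float = 1.0
    jitter: float = 0.003        # within-fixation gaze noise (normalized)
    min_saccade: float = 0.20    # minimum jump between fixation centers
    seed: int = 0


@dataclass
class GazeGroundTruth:
    fixations: list[tuple[float, float, float, float]]  # start, end, cx, cy
    ttff: dict[str, float]       # realized first-look latency per object
    onsets: dict[str, float]
    timeline: LatentTimeline


def _fill_tail(xs: np.ndarray, ys: np.ndarray, i: int) -> None:
    """Fill trailing (< 3) samples with alternating far corners so they can
    neither form a fixation nor merge with the last planted one."""
    corners = ((0.02, 0.02), (0.98, 0.98))
    for k in range(i, len(xs)):
        xs[k], ys[k] = corners[k % 2]


def _draw_fix_center(rng, prev, objects_xy, min_jump, keepout=0.08):
    for _ in range(200):
        c = rng.uniform(0.08, 0.92, size=2)
        if prev is not None and math.hypot(c[0] - prev[0], c[1] - prev[1]) < min_jump:
            continue
        if any(math.hypot(c[0] - ox, c[1] - oy) < keepout for ox, oy in objects_xy):
            continue
        return c
    return np.array([0.5, 0.5])


def simulate_gaze_session(timeline: LatentTimeline, n_objects: int,
                          duration: float, seed: int = 0,
                          spec: GazeGenSpec | None = None,
                          ) -> tuple[GazeStream, ObjectEventTable, GazeGroundTruth]:
    """Fixation–saccade scanpath with object onsets and planted first looks.

    Background fixations avoid a keep-out zone around every object so the
    planted look is provably the first fixation assigned to it; the realized
    first-look latency (planted latency rounded up to the running scanpath
    grid) is returned as ground truth.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    spec = spec or GazeGenSpec(seed=seed)
    rng = np.random.default_rng(spec.seed if spec.seed else seed)
    rate = spec.rate
    dt = 1.0 / rate
    n_total = int(round(duration * rate))

    # objects: static positions, onset leaving room for the look
    obj_ids = [f"AC{k:03d}" for k in range(n_objects)]
    onsets = {}
    obj_pos = {}
    tracks = []
    for oid in obj_ids:
        onsets[oid] = float(rng.uniform(1.0, max(duration - 12.0, 1.5)))
        obj_pos[oid] = tuple(rng.uniform(0.1, 0.9, size=2))
        tt = np.array([onsets[oid], duration])
        tracks.append(ObjectTrack(object_id=oid, onset_s=onsets[oid],
                                  t=tt, x=np.full(2, obj_pos[oid][0]),
                                  y=np.full(2, obj_pos[oid][1])))
    objects = ObjectEventTable(tracks)

    # scheduled looks: onset + state-dependent latency
    look_queue = []
    for oid in obj_ids:
        state = timeline.state_at(onsets[oid])
        mean = (spec.look_latency_high_s if state == HIGH
                else spec.look_latency_low_s)
        lat = max(1.0, float(rng.normal(mean, spec.look_latency_sd_s)))
        look_queue.append((onsets[oid] + lat, oid))
    look_queue.sort()

    xs = np.zeros(n_total)
    ys = np.zeros(n_total)
    gt_fix: list[tuple[float, float, float, float]] = []
    gt_ttff: dict[str, float] = {}

    all_xy = list(obj_pos.values())
    pending_center = None
    i = 0  # sample index
    qi = 0
    while i < n_total:
        t_now = i * dt
        # serve a due look with a fixation on the object
        if qi < len(look_queue) and look_queue[qi][0] <= t_now:
            oid = look_queue[qi][1]
            center = np.array(obj_pos[oid])
            qi += 1
            served = oid
        elif pending_center is not None:
            center = pending_center
            served = None
        else:
            center = _draw_fix_center(rng, None, all_xy, spec.min_saccade)
            served = None
        pending_center = None
        state = timeline.state_at(t_now)
        mean_dur = spec.fix_dur_high_s if state == HIGH else spec.fix_dur_low_s
        n_fix = max(3, int(round(rng.exponential(mean_dur) * rate)) + 1)
        n_fix = min(n_fix, n_total - i)
        if n_fix < 3:
            _fill_tail(xs, ys, i)
            break
        jit = rng.normal(0.0, spec.jitter, size=(n_fix, 2))
        np.clip(jit, -0.015, 0.015, out=jit)
        xs[i:i + n_fix] = center[0] + jit[:, 0]
        ys[i:i + n_fix] = center[1] + jit[:, 1]
        start_t = i * dt
        end_t = (i + n_fix - 1) * dt
        gt_fix.append((start_t, end_t,
                       float(xs[i:i + n_fix].mean()),
                       float(ys[i:i + n_fix].mean())))
        if served is not None and served not in gt_ttff:
            gt_ttff[served] = start_t - onsets[served]
        i += n_fix
        # 2-sample saccade toward the next planned center; steps are at least
        # min_saccade/3 apart so the dispersion box can never absorb them
        if i + 2 <= n_total:
            nxt = _draw_fix_center(rng, center, all_xy, spec.min_saccade)
            for k, frac in enumerate((1 / 3, 2 / 3)):
                xs[i + k] = center[0] + frac * (nxt[0] - center[0])
                ys[i + k] = center[1] + frac * (nxt[1] - center[1])
            i += 2
            pending_center = nxt
        else:
            _fill_tail(xs, ys, i)
            i = n_total

    t = np.arange(n_total) * dt
    stream = GazeStream(t=t, x=np.clip(xs, 0, 1), y=np.clip(ys, 0, 1),
                        valid=np.ones(n_total, dtype=bool), nominal_rate=rate)
    gt = GazeGroundTruth(fixations=gt_fix, ttff=gt_ttff, onsets=dict(onsets),
                         timeline=timeline)
    return stream, objects, gt
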