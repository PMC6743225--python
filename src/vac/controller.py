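"""Adaptive-automation decisions and session summaries.

Every five minutes the controller looks back over the trailing decision
window: when the operator showed mainly Low vigilance there (strictly more
than half of the classified epochs), the level of automation is lowered to
Level 0 to re-engage them; otherwise it is set back to Level 2, the highest
level.  The first interval always starts at Level 2, the nominal operating
condition of the highly automated interface.  The controller emits decisions
as data — it does not simulate the task environment that consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import VigilanceModel, VigilanceTrace, score, smooth_trace
from .config import PipelineConfig
from .errors import IncompatibilityError, PreconditionError
from .preprocess import preprocess
from .session_io import EEGRecording
from .spectral import compute_psd, extract_features

LEVEL2 = "Level2"
LEVEL0 = "Level0"


@dataclass
class LOASchedule:
    """Level-of-automation timeline on a fixed decision cadence.

    ``levels[k]`` holds for the interval [k·period, (k+1)·period); decisions
    are taken at t = period, 2·period, … and recorded with the triggering
    statistic (fraction of Low epochs in the look-back window).
    """

    period: float
    levels: list[str]
    frac_low: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.levels and self.levels[0] != LEVEL2:
            raise PreconditionError("the first interval must start at Level2")

    def level_at(self, t: float) -> str:
        k = min(int(t // self.period), len(self.levels) - 1)
        return self.levels[max(k, 0)]

    @property
    def decision_times(self) -> np.ndarray:
        return self.period * np.arange(1, len(self.levels))

    def switch_count(self) -> int:
        return int(sum(a != b for a, b in zip(self.levels, self.levels[1:])))


@dataclass
class SessionLog:
    """Everything one scoring run produces."""

    trace: VigilanceTrace
    schedule: LOASchedule
    adaptive: bool
    config: PipelineConfig

    def loa_at_epochs(self) -> list[str]:
        return [self.schedule.level_at(t) for t in self.trace.t]


@dataclass
class SessionSummary:
    mean_v_score: float
    low_fraction: float
    window_means: list[float]
    first_window_mean: float
    last_window_mean: float
    relative_change: float
    loa_switches: int
    window_s: float

    def to_dict(self) -> dict:
        return {
            "mean_v_score": self.mean_v_score,
            "low_fraction": self.low_fraction,
            "window_means": self.window_means,
            "first_window_mean": self.first_window_mean,
            "last_window_mean": self.last_window_mean,
            "relative_change": self.relative_change,
            "loa_switches": self.loa_switches,
            "window_s": self.window_s,
        }


# ---------------------------------------------------------------------------
# decisions
# ---------------------------------------------------------------------------

def window_low_fraction(trace: VigilanceTrace, t: float, period: float) -> float:
    """Fraction of Low epochs among non-gap epochs in (t − period, t]."""
    in_win = (trace.t > t - period) & (trace.t <= t) & ~trace.artifact
    n = int(in_win.sum())
    if n == 0:
        return float("nan")
    return float((~trace.state[in_win]).sum() / n)


def decide_loa(trace: VigilanceTrace, t: float, period: float = 300.0,
               prev_level: str = LEVEL2) -> str:
    """Level0 iff strictly more than half of the window's epochs are Low.

    An exact 50/50 split is not "mainly low" and keeps Level2; a window with
    no usable epochs keeps the previous level.
    """
    if t < period - 1e-9:
        raise PreconditionError(
            f"decision at t={t} s before the first full period of {period} s")
    frac = window_low_fraction(trace, t, period)
    if np.isnan(frac):
        return prev_level
    return LEVEL0 if frac > 0.5 else LEVEL2


def build_schedule(trace: VigilanceTrace, period: float = 300.0,
                   adaptive: bool = True,
                   duration: float | None = None) -> LOASchedule:
    if duration is None:
        duration = float(trace.t[-1]) if len(trace) else 0.0
    n_decisions = int(np.floor(duration / period + 1e-9))
    levels = [LEVEL2]
    fracs: list[float] = []
    for k in range(1, n_decisions + 1):
        t = k * period
        fracs.append(window_low_fraction(trace, t, period))
        if adaptive:
            levels.append(decide_loa(trace, t, period, prev_level=levels[-1]))
        else:
            levels.append(LEVEL2)
    return LOASchedule(period=period, levels=levels, frac_low=fracs)


# ---------------------------------------------------------------------------
# end-to-end session
# ---------------------------------------------------------------------------

def run_session(eeg: EEGRecording, model: VigilanceModel,
                cfg: PipelineConfig | None = None,
                adaptive: bool = True) -> SessionLog:
    """Execute the full causal chain on a recording and emit the log.

    filter → blink-correct → epoch → flag → PSD → features → score →
    smooth → classify, then the decision rule on the fixed cadence.  With
    ``adaptive=False`` the schedule stays at Level2 throughout (reference
    condition); the trace is computed identically — the decision rule never
    feeds back into the EEG processing.
    """
    cfg = cfg or PipelineConfig()
    if model.bands is None:
        raise IncompatibilityError("model carries no band definition")
    if adaptive and eeg.duration < cfg.controller.period_s:
        raise PreconditionError(
            f"adaptive mode needs at least one decision period "
            f"({cfg.controller.period_s:.0f} s) of EEG")
    epochs = preprocess(eeg, cfg)
    psd = compute_psd(epochs)
    feats, imap = extract_features(psd, model.bands, log=cfg.features.log)
    if imap != model.index_map:
        raise IncompatibilityError(
            "feature layout of this recording does not match the model "
            "(different montage or band grid)")
    y = score(model, feats)
    artifact = ~epochs.clean_mask
    trace = smooth_trace(epochs.starts, y, cfg.smooth.window_s,
                         model.threshold, artifact)
    schedule = build_schedule(trace, cfg.controller.period_s, adaptive,
                              duration=eeg.duration)
    return SessionLog(trace=trace, schedule=schedule, adaptive=adaptive,
                      config=cfg)


def summarize_session(log: SessionLog) -> SessionSummary:
    """Session-level statistics on the same 5-min grid as the controller."""
    trace = log.trace
    ok = ~trace.artifact
    mean_v = float(trace.v_score[ok].mean()) if ok.any() else float("nan")
    low_frac = float((~trace.state[ok]).sum() / ok.sum()) if ok.any() else float("nan")

    period = log.schedule.period
    duration = float(trace.t[-1]) if len(trace) else 0.0
    n_win = max(1, int(np.ceil((duration - 1e-9) / period)))
    means = []
    for k in range(n_win):
        hi = (k + 1) * period
        sel = ok & (trace.t >= k * period) & (
            (trace.t <= hi) if k == n_win - 1 else (trace.t < hi))
        means.append(float(trace.v_score[sel].mean()) if sel.any() else float("nan"))
    first, last = means[0], means[-1]
    rel = (first - last) / first if first not in (0.0,) and np.isfinite(first) \
        else float("nan")
    return SessionSummary(
        mean_v_score=mean_v, low_fraction=low_frac, window_means=means,
        first_window_mean=first, last_window_mean=last,
        relative_change=float(rel), loa_switches=log.schedule.switch_count(),
        window_s=period)
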