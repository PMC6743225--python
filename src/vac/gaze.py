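"""Dispersion-based fixation detection and gaze vigilance metrics.

A fixation is a maximal run of consecutive valid gaze samples whose bounding
box fits inside an axis-aligned square covering 0.2% of the (normalized)
screen — side √0.002 ≈ 0.0447 — and whose first-to-last span lasts at least
20 ms.  At a 60 Hz sampling rate the duration of an n-sample run is
(n − 1)/60 s, so two samples (16.7 ms) can never qualify; three can.
Invalid samples break runs.

Fixations are assigned to on-screen objects (aircraft, route points) by
nearest interpolated object position at the fixation's start time, within a
configurable radius.  From the assigned fixations come the two vigilance
indicators: fixations per second (general scanning activity) and the
time-to-first-fixation (TTFF) per object — the latency from an object's
onset to the first fixation landing on it, which shortens when the operator
is more vigilant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .session_io import GazeStream, ObjectEventTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fixation:
    start: float
    end: float
    cx: float
    cy: float
    n_samples: int
    object_id: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GazeMetrics:
    fixations_per_second: float
    ttff: dict[str, float]
    n_fixations: int
    duration: float

    def to_dict(self) -> dict:
        return {
            "fixations_per_second": self.fixations_per_second,
            "ttff": dict(self.ttff),
            "n_fixations": self.n_fixations,
            "duration": self.duration,
        }


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_fixations(stream: GazeStream, area_frac: float = 0.002,
                     min_dur: float = 0.020) -> list[Fixation]:
    """I-DT style dispersion grouping over runs of valid samples."""
    if area_frac <= 0 or min_dur <= 0:
        raise ParameterError("area_frac and min_dur must be positive")
    side = math.sqrt(area_frac)
    fixations: list[Fixation] = []
    for seg in _valid_segments(stream.valid):
        t = stream.t[seg]
        x = stream.x[seg]
        y = stream.y[seg]
        fixations.extend(_detect_in_run(t, x, y, side, min_dur))
    return fixations


def _valid_segments(valid: np.ndarray):
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        yield idx[s:e + 1]


def _detect_in_run(t, x, y, side, min_dur):
    out = []
    n = len(t)
    i = 0
    while i < n:
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        j = i
        while j + 1 < n:
            nx, ny = x[j + 1], y[j + 1]
            if (max(xmax, nx) - min(xmin, nx) > side
                    or max(ymax, ny) - min(ymin, ny) > side):
                break
            j += 1
            xmin, xmax = min(xmin, nx), max(xmax, nx)
            ymin, ymax = min(ymin, ny), max(ymax, ny)
        if t[j] - t[i] >= min_dur:
            out.append(Fixation(
                start=float(t[i]), end=float(t[j]),
                cx=float(x[i:j + 1].mean()), cy=float(y[i:j + 1].mean()),
                n_samples=j - i + 1))
            i = j + 1
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# assignment and metrics
# ---------------------------------------------------------------------------

def assign_fixations(fixations: list[Fixation], objects: ObjectEventTable,
                     radius: float = 0.05) -> list[Fixation]:
    """Assign each fixation to the nearest object within ``radius``.

    Object positions are interpolated at the fixation's *start* time (TTFF
    is an onset-latency measure).  Ties go to the nearest object, then to
    the lexicographically lowest id.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    assigned = []
    for fix in fixations:
        best: tuple[float, str] | None = None
        for tr in objects:
            pos = tr.position_at(fix.start)
            if pos is None:
                continue
            d = math.hypot(fix.cx - pos[0], fix.cy - pos[1])
            if d <= radius and (best is None or (d, tr.object_id) < best):
                best = (d, tr.object_id)
        assigned.append(replace(fix, object_id=best[1] if best else None))
    return assigned


def compute_metrics(fixations: list[Fixation], objects: ObjectEventTable,
                    duration: float) -> GazeMetrics:
    """Fixations per second and per-object TTFF.

    Objects never fixated are absent from the TTFF map (missing, never
    zero); an assigned fixation starting before its object's onset would
    yield a negative latency and is excluded with a log message.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    ttff: dict[str, float] = {}
    by_object: dict[str, list[Fixation]] = {}
    for fix in fixations:
        if fix.object_id is not None:
            by_object.setdefault(fix.object_id, []).append(fix)
    for tr in objects:
        cand = sorted(by_object.get(tr.object_id, []), key=lambda f: f.start)
        for fix in cand:
            lat = fix.start - tr.onset_s
            if lat < 0:
                logger.warning(
                    "fixation at %.3f s precedes onset of object %s; excluded",
                    fix.start, tr.object_id)
                continue
            ttff[tr.object_id] = lat
            break
    return GazeMetrics(
        fixations_per_second=len(fixations) / duration,
        ttff=ttff, n_fixations=len(fixations), duration=duration)
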