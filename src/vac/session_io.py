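"""Reading and writing every external artifact of the pipeline.

Formats
-------
EEG        EDF (16-bit, physical dimension must be ``uV``) or a CSV dialect
           with a ``time_s`` column followed by one column per channel (μV).
Gaze       CSV ``t_s,x,y,valid`` at a nominal rate (60 Hz for the supported
           tracker class); x, y are normalized screen coordinates.
Events     CSV long form ``id,onset_s,t_s,x,y``: one onset per object plus a
           position track sampled at arbitrary times.
Model      versioned JSON document (see :func:`save_model`).
Trace      CSV ``t_s,y,v_score,state,loa,artifact``.

EDF files are written by a self-contained minimal writer (single-channel-rate,
1-s data records, zero-padded to a whole record with the true sample count
stored in the reserved header field) and read back through :mod:`mne`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MissingChannelError, ModelIOError, ParameterError

MODEL_FORMAT_VERSION = "vac-model/1"

__all__ = [
    "EEGRecording", "GazeStream", "ObjectEventTable", "ObjectTrack",
    "read_eeg", "write_eeg_csv", "write_edf",
    "read_gaze", "write_gaze_csv",
    "read_events", "write_events_csv",
    "save_model", "load_model",
    "write_trace_csv", "read_trace_csv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG time series, amplitudes in μV.

    ``data`` is a ``(n_channels, n_samples)`` float array; ``fs`` the sampling
    rate in Hz; ``start_time`` an offset in seconds applied to all derived
    timestamps.
    """

    channel_names: list[str]
    data: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ParameterError(
                f"{len(self.channel_names)} channel names but data has "
                f"{self.data.shape[0]} rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ParameterError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str, context: str = "") -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MissingChannelError(name, context) from None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy(self) -> "EEGRecording":
        return EEGRecording(list(self.channel_names), self.data.copy(),
                            self.fs, self.start_time)


@dataclass
class GazeStream:
    """Gaze samples: timestamps (s), normalized x/y in [0, 1], validity."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    nominal_rate: float = 60.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ParameterError("gaze columns must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise FormatError("gaze timestamps must be strictly increasing")
        ok = self.valid
        if ok.any():
            xs, ys = self.x[ok], self.y[ok]
            if xs.min() < 0 or xs.max() > 1 or ys.min() < 0 or ys.max() > 1:
                raise FormatError("valid gaze coordinates must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ObjectTrack:
    """One on-screen object: onset time plus a sampled position track."""

    object_id: str
    onset_s: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) == 0:
            raise ParameterError(f"object {self.object_id!r} has an empty track")
        if not np.all(np.diff(self.t) >= 0):
            raise FormatError(f"object {self.object_id!r} track times not sorted")
        if self.onset_s > self.t[0]:
            raise FormatError(
                f"object {self.object_id!r} onset after first track sample")

    def position_at(self, when: float) -> tuple[float, float] | None:
        """Linearly interpolated position, or None outside the track span."""
        if when < self.t[0] or when > self.t[-1]:
            return None
        return (float(np.interp(when, self.t, self.x)),
                float(np.interp(when, self.t, self.y)))


@dataclass
class ObjectEventTable:
    tracks: list[ObjectTrack] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [tr.object_id for tr in self.tracks]
        if len(set(ids)) != len(ids):
            raise FormatError("object ids must be unique")

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __getitem__(self, object_id: str) -> ObjectTrack:
        for tr in self.tracks:
            if tr.object_id == object_id:
                return tr
        raise KeyError(object_id)


# ---------------------------------------------------------------------------
# EEG CSV dialect
# ---------------------------------------------------------------------------

def read_eeg(path: str | Path, fmt: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or the CSV dialect.

    ``fmt`` may be ``"edf"`` or ``"csv"``; when omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "csv":
        return _read_eeg_csv(path)
    if fmt == "edf":
        return _read_eeg_edf(path)
    raise FormatError(f"unknown EEG format {fmt!r}")


def _read_eeg_csv(path: Path) -> EEGRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("EEG CSV must have a 'time_s' first column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("EEG CSV must contain at least 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise FormatError("EEG CSV timestamps must be increasing")
    if np.abs(dt - med).max() > 0.01 * med:
        raise FormatError("EEG CSV timestamps are non-uniform beyond 1% jitter")
    channels = [c for c in df.columns if c != "time_s"]
    data = df[channels].to_numpy(dtype=float).T
    return EEGRecording(channels, data, fs=1.0 / med, start_time=float(t[0]))


def write_eeg_csv(rec: EEGRecording, path: str | Path,
                  float_format: str = "%.6f") -> None:
    t = rec.start_time + np.arange(rec.n_samples) / rec.fs
    # timestamps need more digits than amplitudes: 6 decimals would alias
    # a 256 Hz grid and corrupt the inferred sampling rate
    df = pd.DataFrame({"time_s": [f"{v:.9f}" for v in t]})
    for i, name in enumerate(rec.channel_names):
        df[name] = rec.data[i]
    df.to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ParameterError(f"EDF field {s!r} exceeds {width} ascii bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a 16-bit EDF file with 1-second data records.

    The signal is zero-padded to a whole number of records; the true sample
    count is stored as ``NSAMP=<n>`` in the reserved header field so that
    :func:`read_eeg` restores the exact length.  Quantization uses a common
    symmetric physical range, so the round-trip error is bounded by
    ``phys_range / 65535`` μV.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    n_records = max(1, math.ceil(n_samp / fs))
    phys_max = float(np.abs(rec.data).max()) if n_samp else 1.0
    phys_max = max(phys_max * 1.0001, 1.0)
    pmax_s = f"{phys_max:.5g}"[:8]
    phys_max = float(pmax_s)  # header truncation defines the actual scale
    if phys_max < np.abs(rec.data).max():
        phys_max = float(np.nextafter(np.abs(rec.data).max(), np.inf))
        pmax_s = f"{phys_max:.6g}"[:8]
        phys_max = float(pmax_s)
    # EDF affine decode: x = (d - dig_min)·(pmax - pmin)/(dig_max - dig_min) + pmin
    cal = 2 * phys_max / 65535

    now = datetime.now(timezone.utc)
    header = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X X X X", 80),
        _edf_ascii("Startdate X X X X", 80),
        _edf_ascii(now.strftime("%d.%m.%y"), 8),
        _edf_ascii(now.strftime("%H.%M.%S"), 8),
        _edf_ascii(256 + 256 * n_ch, 8),
        _edf_ascii(f"NSAMP={n_samp}", 44),
        _edf_ascii(n_records, 8),
        _edf_ascii("1", 8),
        _edf_ascii(n_ch, 4),
    ])
    sig_header = b"".join([
        b"".join(_edf_ascii(name, 16) for name in rec.channel_names),
        b"".join(_edf_ascii("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_ascii("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_ascii(f"-{pmax_s}"[:8], 8) for _ in range(n_ch)),
        b"".join(_edf_ascii(pmax_s, 8) for _ in range(n_ch)),
        b"".join(_edf_ascii(-32768, 8) for _ in range(n_ch)),
        b"".join(_edf_ascii(32767, 8) for _ in range(n_ch)),
        b"".join(_edf_ascii("BP:1-30Hz", 80) for _ in range(n_ch)),
        b"".join(_edf_ascii(fs, 8) for _ in range(n_ch)),
        b"".join(_edf_ascii("", 32) for _ in range(n_ch)),
    ])
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = rec.data
    digital = np.clip(np.rint((padded + phys_max) / cal) - 32768,
                      -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def _peek_edf_header(path: Path) -> tuple[int | None, list[str]]:
    """Return (true sample count if recorded, per-signal physical dims)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError("EDF header truncated")
        reserved = head[192:236].decode("ascii", "replace").strip()
        n_ch = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * n_ch)
        dims_off = 16 * n_ch + 80 * n_ch
        dims = [sig[dims_off + 8 * i: dims_off + 8 * (i + 1)].decode("ascii").strip()
                for i in range(n_ch)]
    nsamp = None
    if reserved.startswith("NSAMP="):
        nsamp = int(reserved.split("=", 1)[1])
    return nsamp, dims


def _read_eeg_edf(path: Path) -> EEGRecording:
    import mne

    nsamp, dims = _peek_edf_header(path)
    bad = [d for d in dims if d not in ("uV", "")]
    if bad:
        raise FormatError(
            f"EDF physical dimension must be 'uV', found {sorted(set(bad))}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned EEG
    if nsamp is not None:
        data = data[:, :nsamp]
    return EEGRecording(list(raw.ch_names), data, fs=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# gaze and events
# ---------------------------------------------------------------------------

def read_gaze(path: str | Path, nominal_rate: float = 60.0) -> GazeStream:
    df = pd.read_csv(path)
    required = {"t_s", "x", "y", "valid"}
    if not required.issubset(df.columns):
        raise FormatError(f"gaze CSV needs columns {sorted(required)}")
    return GazeStream(
        t=df["t_s"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy().astype(bool),
        nominal_rate=nominal_rate,
    )


def write_gaze_csv(stream: GazeStream, path: str | Path) -> None:
    pd.DataFrame({
        "t_s": stream.t, "x": stream.x, "y": stream.y,
        "valid": stream.valid.astype(int),
    }).to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> ObjectEventTable:
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "onset_s", "t_s", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"events CSV needs columns {sorted(required)}")
    tracks = []
    for oid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("t_s")
        onsets = grp["onset_s"].unique()
        if len(onsets) != 1:
            raise FormatError(f"object {oid!r} has conflicting onset times")
        tracks.append(ObjectTrack(
            object_id=str(oid), onset_s=float(onsets[0]),
            t=grp["t_s"].to_numpy(dtype=float),
            x=grp["x"].to_numpy(dtype=float),
            y=grp["y"].to_numpy(dtype=float),
        ))
    return ObjectEventTable(tracks)


def write_events_csv(table: ObjectEventTable, path: str | Path) -> None:
    rows = []
    for tr in table:
        for t, x, y in zip(tr.t, tr.x, tr.y):
            rows.append((tr.object_id, tr.onset_s, t, x, y))
    pd.DataFrame(rows, columns=["id", "onset_s", "t_s", "x", "y"]).to_csv(
        path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a trained vigilance model as a versioned JSON document."""
    doc = {"format": MODEL_FORMAT_VERSION}
    doc.update(model.to_dict())
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    from .classifier import VigilanceModel

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    version = doc.pop("format", None)
    if version != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"unsupported model format {version!r}; expected {MODEL_FORMAT_VERSION!r}")
    try:
        return VigilanceModel.from_dict(doc)
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"malformed model document: {exc}") from exc


# ---------------------------------------------------------------------------
# vigilance trace
# ---------------------------------------------------------------------------

def write_trace_csv(trace, path: str | Path, loa=None) -> None:
    """Write a vigilance trace; ``loa`` optionally maps epoch times to levels."""
    levels = loa if loa is not None else [""] * len(trace.t)
    pd.DataFrame({
        "t_s": trace.t,
        "y": trace.y,
        "v_score": trace.v_score,
        "state": ["High" if s else "Low" for s in trace.state],
        "loa": levels,
        "artifact": trace.artifact.astype(int),
    }).to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path: str | Path):
    from .classifier import VigilanceTrace

    df = pd.read_csv(path)
    return VigilanceTrace(
        t=df["t_s"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        v_score=df["v_score"].to_numpy(dtype=float),
        state=(df["state"] == "High").to_numpy(),
        artifact=df["artifact"].to_numpy().astype(bool),
        threshold=float("nan"),
    )
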