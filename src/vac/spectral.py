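"""Spectral features anchored to the individual alpha frequency (IAF).

Per-epoch power spectral densities come from a single-taper Hann periodogram
whose window spans the whole 2-s epoch, giving a 0.5 Hz frequency grid.
Band edges are not fixed: they are derived from the subject's IAF — the
frequency of the alpha peak in an eyes-closed segment — as

    theta = [IAF − 6, IAF − 2],  alpha = [IAF − 2, IAF + 2],
    beta  = [IAF + 2, IAF + 16]  (all Hz, half-open on the bin grid),

which compensates for the inter-individual drift of the alpha rhythm.  The
feature vector concatenates log-power at every (channel, bin) pair inside
the vigilance-relevant band/region combinations: frontal theta, frontal
beta, centro-parietal alpha, parietal theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import BandConfig
from .errors import CalibrationError, EmptyInputError, MissingChannelError, ParameterError
from .preprocess import EpochSet, make_epochs
from .session_io import EEGRecording


@dataclass
class PSDMatrix:
    """Per-epoch one-sided PSDs: ``power[epoch, channel, bin]`` in μV²/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    channel_names: list[str]
    starts: np.ndarray

    def __len__(self) -> int:
        return self.power.shape[0]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandSet:
    """IAF value, derived band edges, and the montage channel groups."""

    iaf: float
    theta: tuple[float, float]
    alpha: tuple[float, float]
    beta: tuple[float, float]
    frontal: tuple[str, ...] = BandConfig.frontal
    centro_parietal: tuple[str, ...] = BandConfig.centro_parietal
    parietal: tuple[str, ...] = BandConfig.parietal

    @classmethod
    def from_iaf(cls, iaf: float, cfg: BandConfig | None = None) -> "BandSet":
        cfg = cfg or BandConfig()
        bs = cls(
            iaf=float(iaf),
            theta=(iaf + cfg.theta_offsets[0], iaf + cfg.theta_offsets[1]),
            alpha=(iaf + cfg.alpha_offsets[0], iaf + cfg.alpha_offsets[1]),
            beta=(iaf + cfg.beta_offsets[0], iaf + cfg.beta_offsets[1]),
            frontal=tuple(cfg.frontal),
            centro_parietal=tuple(cfg.centro_parietal),
            parietal=tuple(cfg.parietal),
        )
        if bs.theta[0] <= 0:
            raise ParameterError(f"theta low edge {bs.theta[0]:.2f} Hz <= 0")
        return bs

    def to_dict(self) -> dict:
        return {
            "iaf": self.iaf, "theta": list(self.theta), "alpha": list(self.alpha),
            "beta": list(self.beta), "frontal": list(self.frontal),
            "centro_parietal": list(self.centro_parietal),
            "parietal": list(self.parietal),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandSet":
        return cls(iaf=float(d["iaf"]), theta=tuple(d["theta"]),
                   alpha=tuple(d["alpha"]), beta=tuple(d["beta"]),
                   frontal=tuple(d["frontal"]),
                   centro_parietal=tuple(d["centro_parietal"]),
                   parietal=tuple(d["parietal"]))


@dataclass
class FeatureIndexMap:
    """Stable ordering of (channel, bin-frequency) pairs for the features."""

    pairs: list[tuple[str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureIndexMap):
            return NotImplemented
        return len(self.pairs) == len(other.pairs) and all(
            a[0] == b[0] and abs(a[1] - b[1]) < 1e-9
            for a, b in zip(self.pairs, other.pairs))

    def to_list(self) -> list:
        return [[ch, f] for ch, f in self.pairs]

    @classmethod
    def from_list(cls, lst) -> "FeatureIndexMap":
        return cls([(str(ch), float(f)) for ch, f in lst])


# ---------------------------------------------------------------------------
# PSD
# ---------------------------------------------------------------------------

def compute_psd(epochs: EpochSet) -> PSDMatrix:
    """Hann-windowed single-taper periodogram per channel per epoch.

    The window spans the full epoch, so the bin spacing is the reciprocal of
    the epoch length (0.5 Hz for 2-s epochs).
    """
    n_s = epochs.data.shape[2]
    if n_s < 2:
        raise ParameterError("epochs must contain at least 2 samples")
    # direct one-sided Hann periodogram, density scaling (μV²/Hz):
    # P[k] = |FFT(w·x)[k]|² / (fs · Σw²), doubled off DC/Nyquist
    w = signal.get_window("hann", n_s).astype(epochs.data.dtype)
    spec = np.fft.rfft(epochs.data * w, axis=2)
    power = (spec.real ** 2 + spec.imag ** 2) / (epochs.fs * float(w @ w))
    if n_s % 2 == 0:
        power[..., 1:-1] *= 2.0
    else:
        power[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n_s, 1.0 / epochs.fs)
    return PSDMatrix(freqs=freqs, power=power,
                     channel_names=list(epochs.channel_names),
                     starts=epochs.starts)


# ---------------------------------------------------------------------------
# IAF
# ---------------------------------------------------------------------------

def estimate_iaf(eyes_closed: EEGRecording, cfg: BandConfig | None = None,
                 epoch_length: float = 2.0, step: float = 1.0,
                 min_duration: float = 30.0) -> BandSet:
    """Estimate the IAF from an eyes-closed segment and derive the bands.

    The mean PSD over the parietal group is searched for its maximum in the
    alpha range (7–13 Hz by default); the peak must stand out above the
    fitted 1/f background or a :class:`CalibrationError` advises re-recording.
    """
    cfg = cfg or BandConfig()
    if eyes_closed.duration < min_duration:
        raise EmptyInputError(
            f"eyes-closed segment of {eyes_closed.duration:.1f} s; "
            f">= {min_duration:.0f} s required for a stable alpha peak")
    for ch in cfg.parietal:
        if ch not in eyes_closed.channel_names:
            raise MissingChannelError(ch, "IAF estimation needs the parietal group")

    epochs = make_epochs(eyes_closed, epoch_length, step)
    psd = compute_psd(epochs)
    rows = [psd.channel_names.index(ch) for ch in cfg.parietal]
    mean_psd = psd.power[:, rows, :].mean(axis=(0, 1))

    lo, hi = cfg.iaf_search_hz
    in_range = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not in_range.any():
        raise ParameterError("IAF search range contains no frequency bin")
    peak_idx = np.flatnonzero(in_range)[np.argmax(mean_psd[in_range])]
    iaf = float(psd.freqs[peak_idx])

    # 1/f background fitted log-log outside the alpha search range
    bg = (psd.freqs >= 2.0) & (psd.freqs <= 20.0) & ~in_range & (mean_psd > 0)
    if bg.sum() >= 4:
        lf = np.log(psd.freqs[bg])
        lp = np.log(mean_psd[bg])
        slope, intercept = np.polyfit(lf, lp, 1)
        predicted = np.exp(intercept + slope * np.log(iaf))
        if mean_psd[peak_idx] < cfg.iaf_peak_ratio * predicted:
            raise CalibrationError(
                "no alpha peak above the 1/f background in the eyes-closed "
                "segment; re-record the calibration minute")
    return BandSet.from_iaf(iaf, cfg)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Indices of bins whose center lies in the half-open interval [low, high)."""
    return np.flatnonzero((freqs >= band[0] - 1e-9) & (freqs < band[1] - 1e-9))


def feature_index_map(freqs: np.ndarray, bands: BandSet) -> FeatureIndexMap:
    """Deterministic feature ordering: group/band blocks, channels, then bins."""
    pairs: list[tuple[str, float]] = []
    for group, band in ((bands.frontal, bands.theta),
                        (bands.frontal, bands.beta),
                        (bands.centro_parietal, bands.alpha),
                        (bands.parietal, bands.theta)):
        bins = band_bins(freqs, band)
        for ch in group:
            for b in bins:
                pairs.append((ch, float(freqs[b])))
    return FeatureIndexMap(pairs)


def extract_features(psd: PSDMatrix, bands: BandSet, log: bool = True,
                     floor: float = 1e-20) -> tuple[np.ndarray, FeatureIndexMap]:
    """Assemble the per-epoch feature matrix for the band/region pairs.

    Returns ``(features, index_map)`` where ``features`` is
    ``(n_epochs, n_features)``; powers are floored at ``floor`` before the
    log so silent bins stay finite.
    """
    if psd.freqs[-1] < bands.beta[1] - psd.df:
        raise ParameterError("PSD does not cover the beta band")
    for group in (bands.frontal, bands.centro_parietal, bands.parietal):
        for ch in group:
            if ch not in psd.channel_names:
                raise MissingChannelError(ch, "feature extraction")
    imap = feature_index_map(psd.freqs, bands)
    ch_idx = {ch: i for i, ch in enumerate(psd.channel_names)}
    bin_idx = {}
    for _, f in imap.pairs:
        if f not in bin_idx:
            bin_idx[f] = int(np.argmin(np.abs(psd.freqs - f)))
    rows = np.array([ch_idx[ch] for ch, _ in imap.pairs])
    cols = np.array([bin_idx[f] for _, f in imap.pairs])
    feats = psd.power[:, rows, cols]
    if log:
        feats = np.log(np.maximum(feats, floor))
    return feats, imap
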