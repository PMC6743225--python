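"""Shared fixtures: small synthetic recordings built at test time."""

import numpy as np
import pytest

from vac.config import MONTAGE
from vac.session_io import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data_by_channel: dict[str, np.ndarray],
                   fs: float = 256.0) -> EEGRecording:
    names = list(data_by_channel)
    data = np.vstack([data_by_channel[n] for n in names])
    return EEGRecording(names, data, fs=fs)


@pytest.fixture
def small_montage_rec(rng):
    """2 s of low-amplitude noise on the full montage."""
    fs = 256.0
    n = 512
    data = 5.0 * rng.standard_normal((len(MONTAGE), n))
    return EEGRecording(list(MONTAGE), data, fs=fs)


def sine(freq: float, n: int, fs: float = 256.0, amp: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)
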