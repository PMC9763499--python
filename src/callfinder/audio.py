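"""Waveform container and PCM WAV input/output.

Recordings are held as float arrays with amplitudes nominally in [-1, 1];
integer PCM files are rescaled on read so downstream spectral processing is
independent of the on-disk bit depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["Waveform", "read_wav", "write_wav", "to_mono_resample"]


@dataclass(frozen=True)
class Waveform:
    """A mono or multi-channel audio signal.

    Parameters
    ----------
    samples
        Array of shape ``(n,)`` (mono) or ``(n, channels)``, float valued.
    sample_rate
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.size == 0:
            raise ValueError("waveform must be non-empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (n, channels)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length of the signal in seconds."""
        return self.samples.shape[0] / self.sample_rate


_INT_SCALES = {
    np.dtype(np.int16): 2 ** 15,
    np.dtype(np.int32): 2 ** 31,
}


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF/WAV file (8/16/24/32-bit int or float PCM) as floats in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_SCALES:
        data = data.astype(np.float64) / _INT_SCALES[data.dtype]
    else:
        data = data.astype(np.float64)
    return Waveform(samples=data, sample_rate=int(rate))


def write_wav(path: str | Path, w: Waveform, dtype: str = "int16") -> None:
    """Write a waveform as 16-bit PCM (default) or 32-bit float WAV."""
    if dtype == "int16":
        clipped = np.clip(w.samples, -1.0, 1.0)
        data = np.round(clipped * (2 ** 15 - 1)).astype(np.int16)
    elif dtype == "float32":
        data = w.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype: {dtype!r}")
    wavfile.write(str(path), w.sample_rate, data)


def to_mono_resample(w: Waveform, target_sample_rate: int) -> Waveform:
    """Average channels to mono and resample with band-limited interpolation.

    Multi-channel input is reduced by the per-sample channel mean; sampling
    rate conversion uses a polyphase filter (``scipy.signal.resample_poly``),
    i.e. proper band-limited interpolation rather than naive decimation.
    """
    if target_sample_rate <= 0:
        raise ValueError("target_sample_rate must be positive")
    samples = w.samples
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if w.sample_rate != target_sample_rate:
        g = math.gcd(int(target_sample_rate), int(w.sample_rate))
        up = int(target_sample_rate) // g
        down = int(w.sample_rate) // g
        samples = resample_poly(samples, up, down)
        if samples.size == 0:
            raise ValueError("resampling produced an empty signal")
    return Waveform(samples=samples, sample_rate=int(target_sample_rate))
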