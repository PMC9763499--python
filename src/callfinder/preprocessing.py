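"""Spectrogram preprocessing: raw audio to normalized network input.

The pipeline turns a waveform into an ``n_freq_bins x T_net`` matrix in
[0, 1] through eight steps: (1) mono conversion and resampling, (2) STFT
power spectrogram, (3) random intensity/pitch/time augmentation, (4) linear
frequency compression onto the band of interest, (5) SNR-controlled noise
mixing, (6) dB conversion, (7) min/max- or dB-normalization, and (8) random
or centered cropping/zero-padding to the configured sequence length.

Augmentation operates directly on the power spectrogram: intensity scales
the power, pitch and time remap the frequency/time axes by a uniform factor
with nearest-neighbor lookup.  All randomness flows through an explicit
numpy ``Generator`` so identical seeds give bit-identical clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import get_window

from .audio import Waveform, to_mono_resample
from .config import PreprocessingConfig

__all__ = [
    "PowerSpectrogram",
    "NormalizedClip",
    "stft_power",
    "random_augment",
    "compress_frequency",
    "add_noise",
    "to_db",
    "normalize",
    "fit_to_length",
    "preprocess_clip",
]

#: power floor applied before taking log10, far below any signal of interest
DB_FLOOR = 1e-10


@dataclass(frozen=True)
class PowerSpectrogram:
    """``F x T`` nonnegative power matrix with axis metadata.

    ``freq_axis`` gives the center frequency (Hz) of each row, strictly
    increasing; ``time_axis`` gives each frame's start time in seconds.
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        freq = np.asarray(self.freq_axis, dtype=np.float64)
        time = np.asarray(self.time_axis, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (F, T)")
        if np.any(values < 0):
            raise ValueError("power spectrogram must be nonnegative")
        if freq.shape != (values.shape[0],) or time.shape != (values.shape[1],):
            raise ValueError("axis lengths must match the value matrix")
        if freq.size > 1 and not np.all(np.diff(freq) > 0):
            raise ValueError("freq_axis must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "freq_axis", freq)
        object.__setattr__(self, "time_axis", time)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class NormalizedClip:
    """Final network input: ``n_freq_bins x T_net`` values in [0, 1]."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("clip values must be 2-D")
        if values.min() < 0 or values.max() > 1:
            raise ValueError("normalized values must lie in [0, 1]")
        object.__setattr__(self, "values", values)


def stft_power(w: Waveform, cfg: PreprocessingConfig) -> PowerSpectrogram:
    """Magnitude-squared STFT with a Hann window.

    Produces ``F = fft_window_length/2 + 1`` rows and one column per full
    hop of the window inside the signal (no boundary padding); frames that
    would run past the end are dropped.
    """
    samples = np.asarray(w.samples, dtype=np.float64)
    if samples.ndim != 1:
        raise ValueError("stft_power expects a mono waveform")
    win_len, hop = cfg.fft_window_length, cfg.fft_hop
    if win_len > samples.size:
        raise ValueError(
            f"FFT window ({win_len} samples) longer than signal ({samples.size} samples)"
        )
    window = get_window("hann", win_len, fftbins=True)
    n_frames = 1 + (samples.size - win_len) // hop
    frames = np.lib.stride_tricks.sliding_window_view(samples, win_len)[::hop][:n_frames]
    spectrum = np.fft.rfft(frames * window, axis=1)
    power = (spectrum.real ** 2 + spectrum.imag ** 2).T  # (F, T)
    freq_axis = np.fft.rfftfreq(win_len, d=1.0 / w.sample_rate)
    time_axis = np.arange(n_frames) * (hop / w.sample_rate)
    return PowerSpectrogram(values=power, freq_axis=freq_axis, time_axis=time_axis)


def _remap_time(values: np.ndarray, factor: float) -> np.ndarray:
    """Nearest-neighbor time stretch: output column j reads input floor(j/factor)."""
    t_in = values.shape[1]
    t_out = max(1, int(round(t_in * factor)))
    src = np.minimum((np.arange(t_out) / factor).astype(np.int64), t_in - 1)
    return values[:, src]


def _remap_pitch(values: np.ndarray, factor: float) -> np.ndarray:
    """Shift spectral content by ``factor``; row i reads input floor(i/factor).

    The row count is preserved; rows whose source index falls outside the
    input (strong downward shifts) are zero.
    """
    f_in = values.shape[0]
    src = (np.arange(f_in) / factor).astype(np.int64)
    out = np.zeros_like(values)
    valid = src < f_in
    out[valid] = values[src[valid]]
    return out


def random_augment(
    s: PowerSpectrogram, cfg: PreprocessingConfig, rng: np.random.Generator
) -> PowerSpectrogram:
    """Apply one uniform intensity (dB), pitch, and time scaling each.

    Intensity multiplies the power by ``10**(g/10)``; pitch and time remap
    the frequency/time axes with nearest-neighbor lookup.  Degenerate
    intervals (``lo == hi``) yield a fixed factor, so all-identity intervals
    return the input unchanged.
    """
    gain_db = rng.uniform(*cfg.intensity_interval)
    pitch = rng.uniform(*cfg.pitch_interval)
    time_factor = rng.uniform(*cfg.time_interval)
    values = s.values * 10.0 ** (gain_db / 10.0)
    values = _remap_pitch(values, pitch)
    values = _remap_time(values, time_factor)
    if s.time_axis.size > 1:
        frame_dt = s.time_axis[1] - s.time_axis[0]
    else:
        frame_dt = 0.0
    time_axis = np.arange(values.shape[1]) * frame_dt
    return PowerSpectrogram(values=values, freq_axis=s.freq_axis, time_axis=time_axis)


def compress_frequency(s: PowerSpectrogram, cfg: PreprocessingConfig) -> PowerSpectrogram:
    """Linear frequency compression onto ``n_freq_bins`` rows in [f_min, f_max].

    Target frequencies are linearly spaced over the band; each output row
    copies the in-band input row with the nearest frequency.  Rows outside
    [f_min, f_max] never contribute.
    """
    in_band = np.flatnonzero((s.freq_axis >= cfg.f_min) & (s.freq_axis <= cfg.f_max))
    if in_band.size == 0:
        raise ValueError(
            f"no spectrogram rows inside [{cfg.f_min}, {cfg.f_max}] Hz"
        )
    if cfg.n_freq_bins == 1:
        targets = np.array([(cfg.f_min + cfg.f_max) / 2.0])
    else:
        targets = np.linspace(cfg.f_min, cfg.f_max, cfg.n_freq_bins)
    band_freqs = s.freq_axis[in_band]
    nearest = in_band[np.argmin(np.abs(band_freqs[None, :] - targets[:, None]), axis=1)]
    return PowerSpectrogram(
        values=s.values[nearest], freq_axis=targets, time_axis=s.time_axis
    )


def add_noise(
    s: PowerSpectrogram,
    noise: PowerSpectrogram,
    cfg: PreprocessingConfig,
    rng: np.random.Generator,
) -> PowerSpectrogram:
    """Mix a noise spectrogram into ``s`` at a uniformly drawn SNR (dB).

    The noise (already frequency-compressed to the same rows) is first
    pitch/time-augmented, then tiled or randomly cropped to ``s``'s width,
    and finally scaled by alpha such that
    ``10*log10(meanPower(s) / (alpha * meanPower(noise))) = SNR``.
    """
    if noise.values.shape[0] != s.values.shape[0]:
        raise ValueError("noise spectrogram must have the same row count as the signal")
    pitch = rng.uniform(*cfg.pitch_interval)
    time_factor = rng.uniform(*cfg.time_interval)
    noise_vals = _remap_pitch(noise.values, pitch)
    noise_vals = _remap_time(noise_vals, time_factor)

    t_sig = s.values.shape[1]
    t_noise = noise_vals.shape[1]
    if t_noise < t_sig:
        reps = -(-t_sig // t_noise)
        noise_vals = np.tile(noise_vals, (1, reps))[:, :t_sig]
    elif t_noise > t_sig:
        offset = int(rng.integers(0, t_noise - t_sig + 1))
        noise_vals = noise_vals[:, offset : offset + t_sig]

    mean_noise = noise_vals.mean()
    if mean_noise <= 0:
        raise ValueError("noise spectrogram has zero mean power; SNR scaling undefined")
    snr_db = rng.uniform(*cfg.snr_interval)
    alpha = s.values.mean() / (mean_noise * 10.0 ** (snr_db / 10.0))
    return PowerSpectrogram(
        values=s.values + alpha * noise_vals, freq_axis=s.freq_axis, time_axis=s.time_axis
    )


def to_db(s: PowerSpectrogram) -> np.ndarray:
    """Cell-wise ``10*log10(max(power, floor))``; returns a plain dB matrix."""
    return 10.0 * np.log10(np.maximum(s.values, DB_FLOOR))


def normalize(s_db: np.ndarray, cfg: PreprocessingConfig) -> np.ndarray:
    """Map a dB matrix into [0, 1].

    ``minmax`` uses the spectral minimum/maximum (constant input maps to all
    zeros); ``db`` clips ``(x - min_db) / (ref_db - min_db)`` to [0, 1].
    """
    s_db = np.asarray(s_db, dtype=np.float64)
    if cfg.normalization_mode == "minmax":
        lo, hi = s_db.min(), s_db.max()
        if hi == lo:
            return np.zeros_like(s_db)
        return (s_db - lo) / (hi - lo)
    return np.clip((s_db - cfg.min_db) / (cfg.ref_db - cfg.min_db), 0.0, 1.0)


def fit_to_length(
    s: np.ndarray,
    cfg: PreprocessingConfig,
    mode: str = "center",
    rng: Optional[np.random.Generator] = None,
) -> NormalizedClip:
    """Zero-pad or crop a normalized matrix to exactly ``T_net`` columns.

    ``mode='center'`` centers the content (crop offset ``floor((T-T_net)/2)``);
    ``mode='random'`` draws the pad/crop offset uniformly and needs ``rng``.
    """
    if mode not in ("center", "random"):
        raise ValueError("mode must be 'center' or 'random'")
    if mode == "random" and rng is None:
        raise ValueError("mode='random' requires an rng")
    s = np.asarray(s, dtype=np.float64)
    t_net = cfg.t_net
    t = s.shape[1]
    if t == t_net:
        out = s
        offset = 0
    elif t < t_net:
        pad = t_net - t
        offset = pad // 2 if mode == "center" else int(rng.integers(0, pad + 1))
        out = np.zeros((s.shape[0], t_net), dtype=s.dtype)
        out[:, offset : offset + t] = s
    else:
        extra = t - t_net
        offset = extra // 2 if mode == "center" else int(rng.integers(0, extra + 1))
        out = s[:, offset : offset + t_net]
    return NormalizedClip(values=out, provenance={"fit_mode": mode, "fit_offset": int(offset)})


def _prepare_noise_spectrogram(noise: Waveform, cfg: PreprocessingConfig) -> PowerSpectrogram:
    """Mono/resample, STFT and frequency-compress a raw noise excerpt."""
    w = to_mono_resample(noise, cfg.target_sample_rate)
    return compress_frequency(stft_power(w, cfg), cfg)


def preprocess_clip(
    w: Waveform,
    cfg: PreprocessingConfig,
    noise_pool: Optional[Sequence[Waveform]] = None,
    rng: Optional[np.random.Generator] = None,
    fit_mode: Optional[str] = None,
) -> NormalizedClip:
    """Run the full eight-step pipeline on one clip.

    Augmentation and noise mixing run only when ``cfg.augment`` is true (and,
    for noise, when a ``noise_pool`` of raw noise waveforms is given).  The
    default fit mode follows the augmentation flag: random sub-sampling /
    padding while augmenting, centered otherwise.
    """
    if cfg.augment and rng is None:
        raise ValueError("augmentation requires an rng")
    if fit_mode is None:
        fit_mode = "random" if cfg.augment else "center"

    mono = to_mono_resample(w, cfg.target_sample_rate)
    spec = stft_power(mono, cfg)
    if cfg.augment:
        spec = random_augment(spec, cfg, rng)
    spec = compress_frequency(spec, cfg)
    if cfg.augment and noise_pool:
        noise_wave = noise_pool[int(rng.integers(0, len(noise_pool)))]
        noise_spec = _prepare_noise_spectrogram(noise_wave, cfg)
        spec = add_noise(spec, noise_spec, cfg, rng)
    matrix = normalize(to_db(spec), cfg)
    clip = fit_to_length(matrix, cfg, mode=fit_mode, rng=rng)
    clip.provenance["augmented"] = bool(cfg.augment)
    return clip
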