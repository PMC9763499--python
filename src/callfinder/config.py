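"""Species-specific preprocessing hyperparameters and flat key=value config files.

Every animal needs its own spectral settings (sampling rate, FFT window/hop,
frequency band of interest, clip length, normalization levels, augmentation
intervals).  These live in :class:`PreprocessingConfig`; on disk they are a
plain ``key=value`` text file whose keys match the field names, so a config
can be written and versioned without any tooling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

__all__ = ["PreprocessingConfig", "load_key_value", "dump_key_value"]


@dataclass(frozen=True)
class PreprocessingConfig:
    """All tunable knobs of the spectrogram preprocessing pipeline.

    Intervals are ``(lo, hi)`` pairs sampled uniformly during augmentation:
    ``intensity_interval`` in dB, ``pitch_interval``/``time_interval`` as
    unitless axis-scaling factors, ``snr_interval`` in dB for noise mixing.
    """

    target_sample_rate: int = 8000
    fft_window_length: int = 256
    fft_hop: int = 128
    f_min: float = 500.0
    f_max: float = 4000.0
    n_freq_bins: int = 256
    sequence_length: float = 0.5
    normalization_mode: str = "db"  # "minmax" or "db"
    min_db: float = -100.0
    ref_db: float = 20.0
    intensity_interval: Tuple[float, float] = (-6.0, 6.0)
    pitch_interval: Tuple[float, float] = (0.9, 1.1)
    time_interval: Tuple[float, float] = (0.8, 1.2)
    snr_interval: Tuple[float, float] = (-2.0, 10.0)
    augment: bool = False

    def __post_init__(self) -> None:
        if self.target_sample_rate <= 0:
            raise ValueError("target_sample_rate must be positive")
        if self.fft_window_length <= 0 or self.fft_hop <= 0:
            raise ValueError("fft window and hop must be positive")
        if not (self.f_min < self.f_max <= self.target_sample_rate / 2):
            raise ValueError("require f_min < f_max <= target_sample_rate / 2")
        if self.n_freq_bins < 1:
            raise ValueError("n_freq_bins must be >= 1")
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if self.normalization_mode not in ("minmax", "db"):
            raise ValueError("normalization_mode must be 'minmax' or 'db'")
        if self.normalization_mode == "db" and not self.min_db < self.ref_db:
            raise ValueError("require min_db < ref_db")
        for name in ("intensity_interval", "pitch_interval", "time_interval", "snr_interval"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy lo <= hi")
        for name in ("pitch_interval", "time_interval"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} factors must be positive")

    @property
    def t_net(self) -> int:
        """Network input width in STFT frames for the chosen sequence length."""
        return max(1, int(round(self.sequence_length * self.target_sample_rate / self.fft_hop)))

    def replace(self, **changes) -> "PreprocessingConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path) -> "PreprocessingConfig":
        raw = load_key_value(path)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            value = raw[f.name]
            if f.name.endswith("_interval"):
                lo, hi = (float(v) for v in value.replace(",", " ").split())
                kwargs[f.name] = (lo, hi)
            elif f.name == "augment":
                kwargs[f.name] = value.strip().lower() in ("1", "true", "yes")
            elif f.name == "normalization_mode":
                kwargs[f.name] = value.strip()
            elif f.name in ("target_sample_rate", "fft_window_length", "fft_hop", "n_freq_bins"):
                kwargs[f.name] = int(value)
            else:
                kwargs[f.name] = float(value)
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        items = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = f"{value[0]} {value[1]}"
            items[f.name] = value
        dump_key_value(path, items)


def load_key_value(path: str | Path) -> dict:
    """Parse a flat ``key=value`` text file; '#' starts a comment."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def dump_key_value(path: str | Path, items: dict) -> None:
    lines = [f"{k}={v}" for k, v in items.items()]
    Path(path).write_text("\n".join(lines) + "\n")
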