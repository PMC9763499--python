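"""Seeded synthetic bioacoustic corpora for development and validation.

Emulates the structure of a real annotation campaign: short labeled clips
named by the corpus filename convention and distributed over recordings,
plus long continuous tapes with planted vocalization events and an exact
ground-truth selection table.  Signal classes are deliberately simple
(pure tones, linear chirps, amplitude-gated pulse trains) mixed with white
background noise at a controlled mean-power SNR — spectrally well separated
stand-ins for real calls, not realistic vocalization synthesis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import chirp as _chirp

from .audio import Waveform, write_wav
from .dataset import ClipRecord, parse_filename
from .segmentation import Annotation

__all__ = [
    "ClassSpec",
    "SynthSpec",
    "SynthCorpus",
    "generate_clip",
    "generate_corpus",
    "generate_tape",
    "relabel_for_detection",
    "default_detection_spec",
    "default_classification_spec",
]

SIGNAL_KINDS = ("tone", "chirp", "pulse_train", "noise")


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic signal class."""

    name: str
    kind: str
    f0: float = 1000.0
    bandwidth: float = 0.0
    duration_range: Tuple[float, float] = (0.3, 0.8)

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"kind must be one of {SIGNAL_KINDS}")
        if "_" in self.name or not self.name:
            raise ValueError("class names must be non-empty and underscore-free")
        lo, hi = self.duration_range
        if not 0 < lo <= hi:
            raise ValueError("duration_range must be positive with lo <= hi")


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic corpus."""

    sample_rate: int = 8000
    classes: Tuple[ClassSpec, ...] = (
        ClassSpec("target", "tone", f0=1500.0),
        ClassSpec("noise", "noise"),
    )
    snr_db_range: Tuple[float, float] = (0.0, 10.0)
    n_clips_per_class: int = 100
    n_recordings: int = 20
    tape_duration: float = 60.0
    call_density: float = 10.0  # events per minute
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be distinct")
        if sum(c.kind == "noise" for c in self.classes) != 1:
            raise ValueError("exactly one noise class is required")
        if self.n_clips_per_class <= 0 or self.n_recordings <= 0:
            raise ValueError("counts must be positive")
        if self.call_density < 0 or self.tape_duration <= 0:
            raise ValueError("invalid tape parameters")

    @property
    def noise_class(self) -> ClassSpec:
        return next(c for c in self.classes if c.kind == "noise")

    @property
    def signal_classes(self) -> Tuple[ClassSpec, ...]:
        return tuple(c for c in self.classes if c.kind != "noise")


@dataclass
class SynthCorpus:
    root: Path
    records: List[ClipRecord]
    class_names: List[str]


def _raw_signal(cspec: ClassSpec, duration: float, sample_rate: int,
                rng: np.random.Generator) -> np.ndarray:
    n = max(1, int(round(duration * sample_rate)))
    t = np.arange(n) / sample_rate
    phase = rng.uniform(0, 2 * np.pi)
    if cspec.kind == "tone":
        sig = np.sin(2 * np.pi * cspec.f0 * t + phase)
    elif cspec.kind == "chirp":
        f_lo = max(cspec.f0 - cspec.bandwidth / 2, 1.0)
        f_hi = cspec.f0 + cspec.bandwidth / 2
        sig = _chirp(t, f0=f_lo, f1=f_hi, t1=t[-1] if n > 1 else duration, method="linear",
                     phi=np.degrees(phase))
    elif cspec.kind == "pulse_train":
        gate_rate = 10.0  # pulses per second, 50% duty cycle
        gate = ((t * gate_rate) % 1.0) < 0.5
        sig = np.sin(2 * np.pi * cspec.f0 * t + phase) * gate
    else:
        raise ValueError("noise class has no deterministic signal component")
    # short fades avoid broadband clicks at the clip borders
    ramp = min(int(0.005 * sample_rate), n // 4)
    if ramp > 0:
        envelope = np.ones(n)
        envelope[:ramp] = np.linspace(0, 1, ramp)
        envelope[-ramp:] = np.linspace(1, 0, ramp)
        sig = sig * envelope
    return sig


def generate_clip(
    cspec: ClassSpec,
    duration: float,
    snr_db: float,
    sample_rate: int,
    rng: np.random.Generator,
    return_components: bool = False,
):
    """One labeled clip: the class signal mixed with white noise at ``snr_db``.

    SNR is the mean-power ratio in dB between the deterministic signal and
    the additive white noise.  ``snr_db = inf`` yields the pure signal; the
    noise class yields pure white noise.  The result is peak-normalized.
    With ``return_components=True`` the (identically scaled) signal and
    noise components are returned alongside the waveform, so the realized
    power ratio can be verified directly.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = max(1, int(round(duration * sample_rate)))
    if cspec.kind == "noise":
        sig = np.zeros(n)
        noise = rng.standard_normal(n)
    else:
        sig = _raw_signal(cspec, duration, sample_rate, rng)
        if np.isinf(snr_db):
            noise = np.zeros(n)
        else:
            noise = rng.standard_normal(n)
            scale = np.sqrt(np.mean(sig ** 2) / (np.mean(noise ** 2) * 10.0 ** (snr_db / 10.0)))
            noise = scale * noise
    out = sig + noise
    peak = np.max(np.abs(out))
    if peak > 0:
        sig, noise, out = sig / peak * 0.9, noise / peak * 0.9, out / peak * 0.9
    wave = Waveform(samples=out, sample_rate=sample_rate)
    if return_components:
        return wave, sig, noise
    return wave


def generate_corpus(spec: SynthSpec, out_dir: str | Path) -> SynthCorpus:
    """Write a clip corpus named per the filename grammar, seeded and exact.

    Each class gets exactly ``n_clips_per_class`` clips, distributed
    round-robin over ``n_recordings`` shared recording ids.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    records: List[ClipRecord] = []
    for cspec in spec.classes:
        for k in range(spec.n_clips_per_class):
            duration = rng.uniform(*cspec.duration_range)
            snr_db = rng.uniform(*spec.snr_db_range)
            clip = generate_clip(cspec, duration, snr_db, spec.sample_rate, rng)
            recording = f"rec{k % spec.n_recordings:03d}"
            start_ms = k * 2000
            end_ms = start_ms + int(round(duration * 1000))
            name = f"{cspec.name}_{k:04d}_{recording}_{start_ms}_{end_ms}.wav"
            path = out_dir / name
            write_wav(path, clip)
            records.append(parse_filename(str(path)))
    return SynthCorpus(root=out_dir, records=records,
                       class_names=sorted(c.name for c in spec.classes))


def generate_tape(
    spec: SynthSpec, rng: np.random.Generator
) -> Tuple[Waveform, List[Annotation]]:
    """A continuous recording with planted, non-overlapping events.

    Background is continuous white noise; each event's SNR against the
    background is drawn from ``snr_db_range``.  The number of events is
    ``round(call_density * tape_duration / 60)``; placement is uniform at
    random with rejection of overlaps (0.1 s guard), erroring out when the
    requested density cannot be placed.
    """
    sr = spec.sample_rate
    n = int(round(spec.tape_duration * sr))
    background = 0.05 * rng.standard_normal(n)
    p_background = float(np.mean(background ** 2))
    n_events = int(round(spec.call_density * spec.tape_duration / 60.0))
    signal_classes = spec.signal_classes
    if n_events > 0 and not signal_classes:
        raise ValueError("cannot plant events without a signal class")
    longest = max((c.duration_range[1] for c in signal_classes), default=0.0)
    if longest >= spec.tape_duration:
        raise ValueError("tape_duration must exceed the longest event")

    guard = 0.1
    placed: List[Tuple[float, float]] = []
    annotations: List[Annotation] = []
    for _ in range(n_events):
        cspec = signal_classes[int(rng.integers(0, len(signal_classes)))]
        duration = rng.uniform(*cspec.duration_range)
        snr_db = rng.uniform(*spec.snr_db_range)
        for attempt in range(1000):
            start = rng.uniform(0.0, spec.tape_duration - duration)
            if all(start > e + guard or start + duration < s - guard for s, e in placed):
                break
        else:
            raise ValueError("could not place events at the requested call density")
        placed.append((start, start + duration))
        sig = _raw_signal(cspec, duration, sr, rng)
        scale = np.sqrt(p_background * 10.0 ** (snr_db / 10.0) / np.mean(sig ** 2))
        lo = int(round(start * sr))
        background[lo : lo + sig.size] += scale * sig
        annotations.append(
            Annotation(start=start, end=start + duration, label=cspec.name)
        )
    annotations.sort(key=lambda a: a.start)
    peak = np.max(np.abs(background))
    if peak > 1.0:
        background /= peak
    return Waveform(samples=background, sample_rate=sr), annotations


def relabel_for_detection(records: Sequence[ClipRecord],
                          noise_class: str = "noise",
                          target_label: str = "target") -> List[ClipRecord]:
    """Collapse all non-noise classes to a single target label (stage-1 view)."""
    return [
        r if r.label == noise_class else dataclasses.replace(r, label=target_label)
        for r in records
    ]


def default_detection_spec(seed: int = 0) -> SynthSpec:
    """Tone-vs-noise corpus used for the binary detection demonstrations."""
    return SynthSpec(seed=seed)


def default_classification_spec(seed: int = 0) -> SynthSpec:
    """Three-class setting (two call classes plus noise) for multi-stage runs."""
    return SynthSpec(
        classes=(
            ClassSpec("alarm", "tone", f0=1000.0),
            ClassSpec("contact", "chirp", f0=2200.0, bandwidth=800.0),
            ClassSpec("noise", "noise"),
        ),
        seed=seed,
    )
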