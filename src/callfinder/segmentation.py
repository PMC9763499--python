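"""Sliding-window detection over long recordings.

A trained binary (target vs. noise) classifier is slid over the tape with
window length ``epsilon`` and step ``kappa``; each window is preprocessed
(centered, unaugmented) and scored.  Frames whose target probability
exceeds the confidence threshold ``delta`` are concatenated into start/end
annotations.  Optional smoothing marks a negative frame positive when every
temporally overlapping neighbor frame is positive, filling single-frame
gaps inside a call; with non-overlapping windows (``kappa == epsilon``) the
neighbor set is empty and smoothing never fires.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .audio import Waveform
from .config import PreprocessingConfig
from .model import ResNetClassifier, predict_proba
from .preprocessing import preprocess_clip

__all__ = [
    "SlidingWindowConfig",
    "FrameScore",
    "Annotation",
    "make_windows",
    "score_frames",
    "smooth_frames",
    "extract_annotations",
    "write_selection_table",
    "write_raven_table",
    "read_selection_table",
]

_TIME_EPS = 1e-9


@dataclass(frozen=True)
class SlidingWindowConfig:
    window_length_epsilon: float
    step_kappa: float
    threshold_delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.step_kappa <= self.window_length_epsilon:
            raise ValueError("require 0 < step_kappa <= window_length_epsilon")
        if not 0 <= self.threshold_delta <= 1:
            raise ValueError("threshold_delta must lie in [0, 1]")


@dataclass(frozen=True)
class FrameScore:
    """One scored prediction window."""

    start: float
    end: float
    probs: Dict[str, float]
    predicted_label: str

    def overlaps(self, other: "FrameScore") -> bool:
        return self.start < other.end - _TIME_EPS and other.start < self.end - _TIME_EPS


@dataclass(frozen=True)
class Annotation:
    """A contiguous labeled time interval with a confidence."""

    start: float
    end: float
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("annotation requires start < end")

    @property
    def duration(self) -> float:
        return self.end - self.start


def make_windows(duration: float, cfg: SlidingWindowConfig) -> List[Tuple[float, float]]:
    """Window intervals covering [0, duration].

    Full windows start at 0, kappa, 2*kappa, ... while ``start + epsilon <=
    duration``; if uncovered audio remains, one final short window ending at
    ``duration`` is appended (its content is zero-padded for scoring).  A
    recording shorter than epsilon yields a single zero-padded window.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    eps, kappa = cfg.window_length_epsilon, cfg.step_kappa
    if duration < eps - _TIME_EPS:
        return [(0.0, duration)]
    n_full = int(np.floor((duration - eps) / kappa + _TIME_EPS)) + 1
    windows = [(i * kappa, i * kappa + eps) for i in range(n_full)]
    if windows[-1][1] < duration - _TIME_EPS:
        windows.append((windows[-1][0] + kappa, duration))
    return windows


def score_frames(
    network: ResNetClassifier,
    recording: Waveform,
    pcfg: PreprocessingConfig,
    swcfg: SlidingWindowConfig,
    class_names: Sequence[str],
    batch_size: int = 64,
) -> List[FrameScore]:
    """Preprocess and score every sliding window of a recording."""
    samples = recording.samples
    if samples.ndim != 1:
        samples = samples.mean(axis=1)
    sr = recording.sample_rate
    eval_pcfg = pcfg.replace(augment=False)
    eps_samples = int(round(swcfg.window_length_epsilon * sr))
    windows = make_windows(samples.size / sr, swcfg)

    clips = []
    for start, end in windows:
        lo, hi = int(round(start * sr)), int(round(end * sr))
        chunk = samples[lo:hi]
        if chunk.size < eps_samples:  # short final / whole-tape window
            padded = np.zeros(eps_samples, dtype=chunk.dtype)
            padded[: chunk.size] = chunk
            chunk = padded
        clip = preprocess_clip(Waveform(chunk, sr), eval_pcfg, fit_mode="center")
        clips.append(clip.values)

    frames: List[FrameScore] = []
    for batch_start in range(0, len(clips), batch_size):
        probs = predict_proba(network, clips[batch_start : batch_start + batch_size])
        for offset, row in enumerate(probs):
            start, end = windows[batch_start + offset]
            prob_map = {name: float(p) for name, p in zip(class_names, row)}
            frames.append(
                FrameScore(
                    start=start,
                    end=end,
                    probs=prob_map,
                    predicted_label=max(prob_map, key=prob_map.get),
                )
            )
    return frames


def _fill_gaps(frames: Sequence[FrameScore], positive: np.ndarray) -> np.ndarray:
    """One smoothing pass: a negative frame turns positive iff it has
    overlapping neighbors and every one of them is positive (evaluated on
    the original flags, so the pass is order-independent)."""
    out = positive.copy()
    for i, frame in enumerate(frames):
        if positive[i]:
            continue
        neighbors = [j for j, other in enumerate(frames) if j != i and frame.overlaps(other)]
        if neighbors and all(positive[j] for j in neighbors):
            out[i] = True
    return out


def smooth_frames(
    frames: Sequence[FrameScore], target_class: str = "target"
) -> List[FrameScore]:
    """Relabel noise frames as target when all overlapping neighbors are target.

    Only labels change; probabilities are untouched.  The test uses the
    original labels, so flips never cascade.
    """
    frames = sorted(frames, key=lambda f: f.start)
    positive = np.array([f.predicted_label == target_class for f in frames])
    smoothed = _fill_gaps(frames, positive)
    out = []
    for frame, flag in zip(frames, smoothed):
        if flag and frame.predicted_label != target_class:
            frame = dataclasses.replace(frame, predicted_label=target_class)
        out.append(frame)
    return out


def extract_annotations(
    frames: Sequence[FrameScore],
    cfg: SlidingWindowConfig,
    target_class: str = "target",
    smooth: bool = False,
) -> List[Annotation]:
    """Threshold frames at ``delta`` and merge positive runs into annotations.

    A frame is positive iff its target-class probability strictly exceeds
    ``threshold_delta``.  With ``smooth=True`` the neighbor-fill rule is
    applied to the thresholded flags before run merging, so isolated
    sub-threshold frames inside a detected call are absorbed.  Each maximal
    run of positive frames becomes one annotation spanning the first start
    to the last end, with confidence equal to the run's maximum target
    probability.
    """
    frames = sorted(frames, key=lambda f: f.start)
    if not frames:
        return []
    positive = np.array([f.probs[target_class] > cfg.threshold_delta for f in frames])
    if smooth:
        positive = _fill_gaps(frames, positive)
    annotations: List[Annotation] = []
    i = 0
    while i < len(frames):
        if not positive[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(frames) and positive[j + 1]:
            j += 1
        run = frames[i : j + 1]
        annotations.append(
            Annotation(
                start=run[0].start,
                end=run[-1].end,
                label=target_class,
                confidence=max(f.probs[target_class] for f in run),
            )
        )
        i = j + 1
    return annotations


# -- selection tables -------------------------------------------------------

def write_selection_table(annotations: Sequence[Annotation], path: str | Path) -> None:
    """Tab-separated table with columns start_s, end_s, label, confidence."""
    frame = pd.DataFrame(
        {
            "start_s": [a.start for a in annotations],
            "end_s": [a.end for a in annotations],
            "label": [a.label for a in annotations],
            "confidence": [a.confidence for a in annotations],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_raven_table(annotations: Sequence[Annotation], path: str | Path) -> None:
    """Raven-selection-table-compatible dialect."""
    frame = pd.DataFrame(
        {
            "Selection": np.arange(1, len(annotations) + 1),
            "View": "Spectrogram 1",
            "Channel": 1,
            "Begin Time (s)": [a.start for a in annotations],
            "End Time (s)": [a.end for a in annotations],
            "Label": [a.label for a in annotations],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_selection_table(path: str | Path) -> List[Annotation]:
    """Read either dialect written by this module."""
    frame = pd.read_csv(path, sep="\t")
    if "Begin Time (s)" in frame.columns:
        starts, ends = frame["Begin Time (s)"], frame["End Time (s)"]
        labels = frame["Label"]
        confidences = frame.get("Confidence", pd.Series([1.0] * len(frame)))
    else:
        starts, ends = frame["start_s"], frame["end_s"]
        labels = frame["label"]
        confidences = frame.get("confidence", pd.Series([1.0] * len(frame)))
    return [
        Annotation(start=float(s), end=float(e), label=str(l), confidence=float(c))
        for s, e, l, c in zip(starts, ends, labels, confidences)
    ]
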