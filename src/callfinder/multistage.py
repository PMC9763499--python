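"""Second-stage multi-class classification and the detect-then-classify pipeline.

Pre-segmented clips (outputs of the detection stage, or any labeled excerpt)
are classified by a multi-class network.  Because the preceding detector has
a low false-positive rate, a *noise* prediction is only trusted when its
confidence exceeds a threshold (default 0.85); otherwise the runner-up class
wins the frame.  Clips longer than the window are scored with a sliding,
full-windows-only pass, and each frame adds its voted class's probability to
that class's cumulative mass; the class with the largest mass is the final
decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .audio import Waveform
from .config import PreprocessingConfig
from .model import ResNetClassifier, predict_proba
from .preprocessing import preprocess_clip
from .segmentation import (
    Annotation,
    SlidingWindowConfig,
    extract_annotations,
    score_frames,
)

__all__ = ["NoiseOverrideConfig", "ClassifierDecision", "frame_vote", "accumulate_votes",
           "classify_clip", "detect_then_classify"]


@dataclass(frozen=True)
class NoiseOverrideConfig:
    noise_threshold: float = 0.85
    noise_class_name: str = "noise"

    def __post_init__(self) -> None:
        if not 0 <= self.noise_threshold <= 1:
            raise ValueError("noise_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ClassifierDecision:
    clip_id: str
    mass: Dict[str, float]
    chosen_class: str
    n_frames: int


def frame_vote(probs: Dict[str, float], cfg: NoiseOverrideConfig) -> Tuple[str, float]:
    """Winning class of one frame under the noise-override rule.

    The argmax class wins outright unless it is noise with confidence at or
    below the threshold, in which case the second-largest class is taken
    instead.  Ties break by class name for determinism.
    """
    if cfg.noise_class_name not in probs:
        raise ValueError(f"noise class {cfg.noise_class_name!r} missing from probabilities")
    ranked = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    best_class, best_prob = ranked[0]
    if best_class != cfg.noise_class_name:
        return best_class, best_prob
    if best_prob > cfg.noise_threshold:
        return best_class, best_prob
    return ranked[1]


def accumulate_votes(
    prob_maps: Sequence[Dict[str, float]],
    cfg: NoiseOverrideConfig,
    class_names: Sequence[str],
) -> Tuple[Dict[str, float], str]:
    """Cumulative probability-mass voting over a clip's frame probabilities.

    Each frame contributes its voted class's probability (after the noise
    override) to that class's mass.  Returns the per-class masses and the
    winning class; final ties break by class name.
    """
    if not prob_maps:
        raise ValueError("need at least one frame")
    mass = {name: 0.0 for name in class_names}
    for probs in prob_maps:
        voted, prob = frame_vote(probs, cfg)
        mass[voted] += prob
    chosen = min(mass, key=lambda name: (-mass[name], name))
    return mass, chosen


def classify_clip(
    network: ResNetClassifier,
    clip: Waveform,
    pcfg: PreprocessingConfig,
    swcfg: SlidingWindowConfig,
    ocfg: NoiseOverrideConfig,
    class_names: Sequence[str],
    clip_id: str = "",
) -> ClassifierDecision:
    """Classify one pre-segmented clip by cumulative probability-mass voting.

    A clip shorter than the window is scored as a single window equal to the
    clip (padded/cropped by the standard centered fit).  Longer clips are
    scored at starts ``0, kappa, 2*kappa, ...`` keeping full windows only —
    no zero-padded partial window — so border content never produces a
    spurious frame.
    """
    samples = clip.samples if clip.samples.ndim == 1 else clip.samples.mean(axis=1)
    sr = clip.sample_rate
    duration = samples.size / sr
    eval_pcfg = pcfg.replace(augment=False)
    eps, kappa = swcfg.window_length_epsilon, swcfg.step_kappa

    if duration < eps - 1e-9:
        windows = [(0.0, duration)]
    else:
        n_full = int(np.floor((duration - eps) / kappa + 1e-9)) + 1
        windows = [(i * kappa, i * kappa + eps) for i in range(n_full)]

    clips = []
    for start, end in windows:
        chunk = samples[int(round(start * sr)) : int(round(end * sr))]
        clips.append(preprocess_clip(Waveform(chunk, sr), eval_pcfg, fit_mode="center").values)
    probs = predict_proba(network, clips)

    prob_maps = [{name: float(p) for name, p in zip(class_names, row)} for row in probs]
    mass, chosen = accumulate_votes(prob_maps, ocfg, class_names)
    return ClassifierDecision(clip_id=clip_id, mass=mass, chosen_class=chosen,
                              n_frames=len(windows))


def detect_then_classify(
    det_network: ResNetClassifier,
    cls_network: ResNetClassifier,
    recording: Waveform,
    pcfg_det: PreprocessingConfig,
    pcfg_cls: PreprocessingConfig,
    swcfg: SlidingWindowConfig,
    ocfg: NoiseOverrideConfig,
    det_class_names: Sequence[str] = ("noise", "target"),
    cls_class_names: Sequence[str] = (),
    target_class: str = "target",
    smooth: bool = True,
) -> List[Tuple[Annotation, ClassifierDecision]]:
    """Two-stage pipeline: detect target intervals, then classify each excerpt."""
    frames = score_frames(det_network, recording, pcfg_det, swcfg, det_class_names)
    detections = extract_annotations(frames, swcfg, target_class=target_class, smooth=smooth)
    samples = recording.samples if recording.samples.ndim == 1 else recording.samples.mean(axis=1)
    sr = recording.sample_rate

    results: List[Tuple[Annotation, ClassifierDecision]] = []
    for k, ann in enumerate(detections):
        chunk = samples[int(round(ann.start * sr)) : int(round(ann.end * sr))]
        decision = classify_clip(
            cls_network,
            Waveform(chunk, sr),
            pcfg_cls,
            swcfg,
            ocfg,
            cls_class_names,
            clip_id=f"detection_{k:04d}",
        )
        results.append((ann, decision))
    return results
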