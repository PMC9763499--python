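"""Modified 18-layer residual spectrogram classifier.

The architecture is a standard ResNet18 with two changes suited to
spectrogram input: the stem's max-pooling layer is removed (so early
time-frequency resolution is kept) and the global average pooling is
adaptive, so any sequence length maps to the same 512-dimensional feature
vector before the n-class linear head.  Total downsampling is a factor of
16 in both the frequency and the time axis (one stride-2 stem convolution
plus three stride-2 stage transitions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .config import PreprocessingConfig
from .preprocessing import NormalizedClip

__all__ = ["NetworkSpec", "ResNetClassifier", "build_network", "predict_proba",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the residual classifier."""

    n_classes: int
    input_shape: Tuple[int, int]  # (n_freq_bins, T_net)
    widths: Tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks: Tuple[int, int, int, int] = (2, 2, 2, 2)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.widths) != 4 or len(self.blocks) != 4:
            raise ValueError("widths and blocks must have four stages")


class ResNetClassifier:
    """Stem (7x7/2 conv, no max-pool) + four residual stages + GAP + head."""

    def __init__(self, spec: NetworkSpec, rng: Optional[np.random.Generator] = None) -> None:
        rng = rng or np.random.default_rng()
        self.spec = spec
        w = spec.widths
        self.stem = nn.Sequential(
            nn.Conv2d(1, w[0], 7, stride=2, padding=3, rng=rng, name="stem"),
            nn.BatchNorm2d(w[0], name="stem_bn"),
            nn.ReLU(),
        )
        stages: List[nn.Layer] = []
        in_c = w[0]
        for stage_idx, (width, n_blocks) in enumerate(zip(w, spec.blocks)):
            stride = 1 if stage_idx == 0 else 2
            for block_idx in range(n_blocks):
                stages.append(
                    nn.BasicBlock(
                        in_c,
                        width,
                        stride if block_idx == 0 else 1,
                        rng,
                        name=f"s{stage_idx}b{block_idx}",
                    )
                )
                in_c = width
        self.stages = nn.Sequential(*stages)
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Linear(w[3], spec.n_classes, rng=rng, name="head")
        self._feature_map_shape: Optional[Tuple[int, int]] = None

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (N, F, T) or (N, 1, F, T)."""
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[2:]} does not match network input {self.spec.input_shape}"
            )
        features = self.stages.forward(self.stem.forward(x, train), train)
        self._feature_map_shape = features.shape[2:]
        pooled = self.pool.forward(features, train)
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dy = self.pool.backward(dy)
        dy = self.stages.backward(dy)
        self.stem.backward(dy)

    @property
    def feature_map_shape(self) -> Optional[Tuple[int, int]]:
        """(F', T') of the last residual stage's feature maps, after a forward pass."""
        return self._feature_map_shape

    @property
    def feature_dim(self) -> int:
        return self.spec.widths[3]

    # -- bookkeeping -------------------------------------------------------
    def parameters(self) -> List[nn.Param]:
        return self.stem.parameters() + self.stages.parameters() + self.head.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_arrays(self):
        return self.stem.state_arrays() + self.stages.state_arrays() + self.head.state_arrays()

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        arrays = list(arrays)
        self.stem.load_state(arrays)
        self.stages.load_state(arrays)
        self.head.load_state(arrays)
        if arrays:
            raise ValueError("checkpoint holds more arrays than the network expects")

    def copy_state(self) -> List[np.ndarray]:
        return [arr.copy() for _, arr in self.state_arrays()]


def build_network(spec: NetworkSpec, seed: Optional[int] = None) -> ResNetClassifier:
    """Construct the classifier with Kaiming-initialized convolutions."""
    return ResNetClassifier(spec, rng=np.random.default_rng(seed))


def _clip_batch(clips: Sequence[NormalizedClip | np.ndarray]) -> np.ndarray:
    arrays = [c.values if isinstance(c, NormalizedClip) else np.asarray(c) for c in clips]
    return np.stack(arrays).astype(nn.DTYPE)


def predict_proba(network: ResNetClassifier, clips: Sequence[NormalizedClip | np.ndarray],
                  batch_size: int = 32) -> np.ndarray:
    """Per-class probabilities (rows sum to 1) in evaluation mode."""
    batch = _clip_batch(clips)
    out = []
    for start in range(0, batch.shape[0], batch_size):
        logits = network.forward(batch[start : start + batch_size], train=False)
        out.append(nn.softmax(logits.astype(np.float64)))
    return np.concatenate(out, axis=0)


def save_checkpoint(
    path: str | Path,
    network: ResNetClassifier,
    pcfg: PreprocessingConfig,
    class_names: Sequence[str],
) -> None:
    """Persist weights plus everything needed for self-describing prediction."""
    if len(class_names) != network.spec.n_classes:
        raise ValueError("class_names must match n_classes")
    meta = {
        "spec": asdict(network.spec),
        "preprocessing": {k: list(v) if isinstance(v, tuple) else v
                          for k, v in asdict(pcfg).items()},
        "class_names": list(class_names),
    }
    arrays = {f"arr_{i:04d}": arr for i, (_, arr) in enumerate(network.state_arrays())}
    with open(path, "wb") as fh:  # keep the exact filename (np.savez would append .npz)
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path):
    """Load (network, preprocessing config, class names) from a checkpoint file."""
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[k] for k in sorted(k for k in data.files if k.startswith("arr_"))]
    spec_dict = meta["spec"]
    spec = NetworkSpec(
        n_classes=spec_dict["n_classes"],
        input_shape=tuple(spec_dict["input_shape"]),
        widths=tuple(spec_dict["widths"]),
        blocks=tuple(spec_dict["blocks"]),
    )
    network = build_network(spec, seed=0)
    network.load_state(arrays)
    pdict = {k: tuple(v) if isinstance(v, list) else v for k, v in meta["preprocessing"].items()}
    pcfg = PreprocessingConfig(**pdict)
    return network, pcfg, list(meta["class_names"])
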