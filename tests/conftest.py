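"""Shared fixtures: synthetic corpora and trained demonstration models.

Training fixtures are session-scoped so the (CPU-sized) networks are fitted
once and reused by the sliding-window, pipeline, and acceptance tests.  The
desk-scale study conditions are fixed here: 64 frequency bins, 0.5 s
sequence length, a narrow (16, 32, 64, 128) residual network, Adam at 1e-3,
at most 20 epochs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from callfinder.config import PreprocessingConfig
from callfinder.dataset import split_by_recording
from callfinder.model import NetworkSpec, build_network
from callfinder.synthetic import (
    default_classification_spec,
    default_detection_spec,
    generate_corpus,
    generate_tape,
    relabel_for_detection,
)
from callfinder.training import TrainingConfig, evaluate_split, train

E2E_SEED = 1
E2E_WIDTHS = (16, 32, 64, 128)
E2E_PCFG = PreprocessingConfig(n_freq_bins=64, augment=True, normalization_mode="minmax")
E2E_TCFG = TrainingConfig(
    learning_rate=1e-3, max_epochs=20, early_stop_patience_epochs=6, seed=E2E_SEED
)


def _network(n_classes: int, seed: int):
    spec = NetworkSpec(
        n_classes=n_classes, input_shape=(E2E_PCFG.n_freq_bins, E2E_PCFG.t_net),
        widths=E2E_WIDTHS,
    )
    return build_network(spec, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def detection_corpus(tmp_path_factory):
    """Tone-vs-noise clip corpus (100 clips per class over 20 recordings)."""
    spec = default_detection_spec(seed=E2E_SEED)
    return spec, generate_corpus(spec, tmp_path_factory.mktemp("det_corpus"))


@pytest.fixture(scope="session")
def trained_detector(detection_corpus):
    """Binary detector trained on the tone-vs-noise corpus, plus its metrics."""
    spec, corpus = detection_corpus
    splits = split_by_recording(corpus.records, seed=E2E_SEED)
    class_names = ["noise", "target"]
    network = _network(2, seed=E2E_SEED)
    network, history = train(network, splits, E2E_PCFG, E2E_TCFG, class_names=class_names)
    metrics = evaluate_split(network, splits.test, E2E_PCFG, class_names,
                             positive_class="target")
    return {
        "network": network,
        "class_names": class_names,
        "pcfg": E2E_PCFG,
        "splits": splits,
        "history": history,
        "test_metrics": metrics,
        "spec": spec,
    }


@pytest.fixture(scope="session")
def detection_tape(detection_corpus):
    """60 s tape with 10 planted tone calls and its exact ground truth."""
    spec, _ = detection_corpus
    tape_spec = dataclasses.replace(spec, tape_duration=60.0, call_density=10.0)
    return generate_tape(tape_spec, np.random.default_rng(E2E_SEED + 100))


@pytest.fixture(scope="session")
def three_class_setup(tmp_path_factory):
    """Detector + 3-class classifier for the two-stage pipeline, with a tape."""
    spec = default_classification_spec(seed=E2E_SEED + 1)
    corpus = generate_corpus(spec, tmp_path_factory.mktemp("cls_corpus"))

    det_splits = split_by_recording(relabel_for_detection(corpus.records), seed=E2E_SEED)
    det_net = _network(2, seed=E2E_SEED)
    det_net, _ = train(det_net, det_splits, E2E_PCFG, E2E_TCFG,
                       class_names=["noise", "target"])

    cls_splits = split_by_recording(corpus.records, seed=E2E_SEED)
    cls_net = _network(3, seed=E2E_SEED + 1)
    cls_net, _ = train(cls_net, cls_splits, E2E_PCFG, E2E_TCFG,
                       class_names=corpus.class_names)

    tape_spec = dataclasses.replace(spec, tape_duration=60.0, call_density=10.0)
    tape, ground_truth = generate_tape(tape_spec, np.random.default_rng(E2E_SEED + 200))
    return {
        "detector": det_net,
        "classifier": cls_net,
        "det_classes": ["noise", "target"],
        "cls_classes": corpus.class_names,
        "pcfg": E2E_PCFG,
        "tape": tape,
        "ground_truth": ground_truth,
        "corpus": corpus,
    }
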