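"""Labeled clip corpora: filename parsing and recording-exclusive splits.

Clips are WAV files named ``LABEL_ID_RECORDING_STARTms_ENDms.wav``; the label
may not contain underscores, the clip id may.  A class subdirectory, when
present, overrides the filename label.  Splitting keeps every recording in
exactly one partition so that evaluation never sees acoustic context from a
training tape.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ClipRecord",
    "DatasetSplit",
    "parse_filename",
    "scan_corpus",
    "split_by_recording",
    "write_split_manifests",
    "read_manifest",
]

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)
_PARTS = ("train", "validation", "test")


@dataclass(frozen=True)
class ClipRecord:
    """One labeled audio clip and where it came from."""

    path: str
    label: str
    recording_id: str
    start_ms: int
    end_ms: int

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be non-empty")
        if not self.start_ms < self.end_ms:
            raise ValueError(f"{self.path}: require start_ms < end_ms")


@dataclass
class DatasetSplit:
    train: List[ClipRecord]
    validation: List[ClipRecord]
    test: List[ClipRecord]
    fractions: Tuple[float, float, float] = DEFAULT_FRACTIONS

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def sizes(self) -> Tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def parse_filename(name: str, label_override: str | None = None) -> ClipRecord:
    """Parse ``LABEL_ID_RECORDING_STARTms_ENDms.wav`` into a :class:`ClipRecord`.

    The clip id may itself contain underscores; label and recording id may
    not.  Raises ``ValueError`` naming the file on any grammar violation.
    """
    stem = Path(name).name
    if not stem.lower().endswith(".wav"):
        raise ValueError(f"clip filename must end in .wav: {name!r}")
    parts = stem[:-4].split("_")
    if len(parts) < 5:
        raise ValueError(
            f"clip filename {name!r} does not match LABEL_ID_RECORDING_STARTms_ENDms.wav"
        )
    label, recording = parts[0], parts[-3]
    start_raw, end_raw = parts[-2], parts[-1]
    if not (start_raw.isdigit() and end_raw.isdigit()):
        raise ValueError(f"clip filename {name!r}: start/end must be integer milliseconds")
    if not label or not recording:
        raise ValueError(f"clip filename {name!r}: empty label or recording id")
    return ClipRecord(
        path=str(name),
        label=label_override or label,
        recording_id=recording,
        start_ms=int(start_raw),
        end_ms=int(end_raw),
    )


def scan_corpus(root: str | Path) -> List[ClipRecord]:
    """Collect all ``*.wav`` clips below ``root``.

    Clips directly under ``root`` take their label from the filename; clips
    inside a first-level subdirectory take the subdirectory name as label.
    """
    root = Path(root)
    records: List[ClipRecord] = []
    for path in sorted(root.rglob("*.wav")):
        rel = path.relative_to(root)
        override = rel.parts[0] if len(rel.parts) > 1 else None
        records.append(parse_filename(str(path), label_override=override))
    if not records:
        raise ValueError(f"no .wav clips found under {root}")
    return records


def split_by_recording(
    records: Sequence[ClipRecord],
    fractions: Tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> DatasetSplit:
    """Partition clips 70/15/15 (by default) without splitting any recording.

    Per class, recordings are shuffled with the seed and assigned greedily to
    the partition whose clip-count deficit against its target fraction is
    largest, ties resolved in train/validation/test order.  A recording that
    already received a partition from an earlier class keeps it, so the
    exclusivity invariant holds corpus-wide.
    """
    if not records:
        raise ValueError("cannot split an empty corpus")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    recording_ids = {r.recording_id for r in records}
    if len(recording_ids) < 3:
        raise ValueError(
            f"need at least 3 distinct recordings for an exclusive split, got {len(recording_ids)}"
        )

    rng = np.random.default_rng(seed)
    by_class: Dict[str, List[ClipRecord]] = collections.defaultdict(list)
    for r in records:
        by_class[r.label].append(r)

    assignment: Dict[str, int] = {}  # recording_id -> partition index
    part_recordings = [0, 0, 0]
    n_unassigned = len(recording_ids)
    for label in sorted(by_class):
        class_records = by_class[label]
        by_rec: Dict[str, List[ClipRecord]] = collections.defaultdict(list)
        for r in class_records:
            by_rec[r.recording_id].append(r)
        targets = [f * len(class_records) for f in fractions]
        counts = [0.0, 0.0, 0.0]
        pending = []
        for rec_id in sorted(by_rec):
            if rec_id in assignment:
                counts[assignment[rec_id]] += len(by_rec[rec_id])
            else:
                pending.append(rec_id)
        order = rng.permutation(len(pending))
        for idx in order:
            rec_id = pending[idx]
            deficits = [targets[p] - counts[p] for p in range(3)]
            # never leave a partition empty: once the remaining recordings are
            # only just enough for the still-empty partitions, fill those first
            empty = [p for p in range(3) if part_recordings[p] == 0]
            if empty and n_unassigned <= len(empty):
                part = max(empty, key=lambda p: (deficits[p], -p))
            else:
                part = int(np.argmax(deficits))  # first maximum: train-first ties
            assignment[rec_id] = part
            counts[part] += len(by_rec[rec_id])
            part_recordings[part] += 1
            n_unassigned -= 1

    parts: Tuple[List[ClipRecord], ...] = ([], [], [])
    for r in records:
        parts[assignment[r.recording_id]].append(r)
    return DatasetSplit(
        train=parts[0], validation=parts[1], test=parts[2], fractions=tuple(fractions)
    )


def write_split_manifests(split: DatasetSplit, out_dir: str | Path) -> None:
    """Write train.csv / val.csv / test.csv with path,label,recording_id columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, part in zip(("train", "val", "test"), split):
        frame = pd.DataFrame(
            {
                "path": [r.path for r in part],
                "label": [r.label for r in part],
                "recording_id": [r.recording_id for r in part],
            }
        )
        frame.to_csv(out_dir / f"{name}.csv", index=False)


def read_manifest(path: str | Path) -> List[ClipRecord]:
    frame = pd.read_csv(path)
    return [parse_filename(str(p), label_override=str(lab)) for p, lab in zip(frame["path"], frame["label"])]
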