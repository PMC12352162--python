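"""Cutting task-locked epochs into labeled 2-D trial tensors.

A trial tensor has one row per contact for broadband input, or two rows per
contact (contact-major, high-gamma row then beta row) for convolved-burst
input, and a fixed number of time samples.  Labels are binary: subsequently
recalled vs. forgotten for encoding trials, encoding vs. recall for
memory-state trials, good vs. poor session for whole recall epochs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .simulate import TaskSchedule

__all__ = [
    "TensorKind",
    "LabeledDataset",
    "extract_encoding_epochs",
    "extract_recall_segments",
    "build_state_dataset",
    "extract_recall_epochs",
    "smallest_mode",
    "save_dataset",
    "load_dataset",
]


class TensorKind:
    ENC_BURST = "ENC_BURST"
    ENC_BROADBAND = "ENC_BROADBAND"
    STATE_SEGMENT = "STATE_SEGMENT"
    RECALL_EPOCH = "RECALL_EPOCH"


@dataclass
class LabeledDataset:
    """A stack of equally shaped trial tensors with binary labels."""

    tensors: np.ndarray  # (n_trials, n_rows, n_samples) float32
    labels: np.ndarray  # (n_trials,) int {0, 1}
    trial_ids: list
    kind: str
    fs_hz: float
    row_names: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    #: optional per-trial group (e.g. list index) for group-aware folds;
    #: segments cut from one recall window can share samples, so holding
    #: out whole lists avoids content leakage across folds
    groups: np.ndarray | None = None

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.tensors.ndim != 3:
            raise ValueError("tensors must be (n_trials, n_rows, n_samples)")
        if len(self.labels) != len(self.tensors):
            raise ValueError("labels and tensors must align")

    def __len__(self) -> int:
        return len(self.tensors)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tensors.shape[1:]

    @property
    def class_balance(self) -> float:
        return float(self.labels.mean()) if len(self) else float("nan")

    @property
    def is_trainable(self) -> bool:
        """Training needs at least one example of each class."""
        return len(np.unique(self.labels)) == 2


def _cut_epochs(rows: np.ndarray, fs_hz: float, onsets_s, window_s: float):
    """Slice fixed-length epochs; epochs running past the end are dropped."""
    n = rows.shape[-1]
    length = int(round(window_s * fs_hz))
    tensors, kept = [], []
    for k, onset in enumerate(onsets_s):
        i0 = int(round(onset * fs_hz))
        if i0 + length > n:
            warnings.warn(f"epoch {k} at {onset:.2f}s extends past the recording; dropped")
            continue
        tensors.append(rows[:, i0:i0 + length])
        kept.append(k)
    if not tensors:
        raise ValueError("no epoch fits inside the recording")
    return np.stack(tensors), kept


def extract_encoding_epochs(schedule: TaskSchedule, recalled: np.ndarray,
                            rows: np.ndarray, fs_hz: float,
                            window_s: float = 3.0,
                            kind: str = TensorKind.ENC_BURST,
                            provenance: str = "") -> LabeledDataset:
    """One stimulus-locked tensor per word event, starting at word onset and
    lasting ``window_s`` (default 3 s); labeled by subsequent recall."""
    onsets = [w.onset_s for w in schedule.word_events]
    tensors, kept = _cut_epochs(rows, fs_hz, onsets, window_s)
    labels = np.asarray(recalled, dtype=int)[kept]
    groups = np.asarray([schedule.word_events[k].list_index for k in kept])
    return LabeledDataset(tensors, labels, trial_ids=list(kept), kind=kind,
                          fs_hz=fs_hz, provenance=[provenance] if provenance else [],
                          groups=groups)


def extract_recall_segments(schedule: TaskSchedule, rows: np.ndarray,
                            fs_hz: float, window_s: float = 3.0,
                            per_list: int = 12, seed: int = 0,
                            provenance: str = "") -> LabeledDataset:
    """Randomly placed ``window_s`` segments inside each 30-s recall window.

    ``per_list`` defaults to 12, matching the number of word-encoding trials
    per list so the memory-state dataset is class balanced.  Segments may
    overlap each other.
    """
    rng = np.random.default_rng(seed)
    onsets, ids = [], []
    for li, (r_on, r_dur) in enumerate(schedule.recall_windows):
        hi = r_on + r_dur - window_s
        for j in range(per_list):
            onsets.append(float(rng.uniform(r_on, hi)))
            ids.append(("recall", li, j))
    tensors, kept = _cut_epochs(rows, fs_hz, onsets, window_s)
    labels = np.zeros(len(kept), dtype=int)
    return LabeledDataset(tensors, labels, trial_ids=[ids[k] for k in kept],
                          kind=TensorKind.STATE_SEGMENT, fs_hz=fs_hz,
                          provenance=[provenance] if provenance else [],
                          groups=np.asarray([ids[k][1] for k in kept]))


def build_state_dataset(encoding: LabeledDataset, recall: LabeledDataset,
                        seed: int = 0) -> LabeledDataset:
    """Pool encoding (label 1) and recall (label 0) tensors, order randomized."""
    if encoding.shape != recall.shape:
        raise ValueError(
            f"tensor shapes differ: {encoding.shape} vs {recall.shape}")
    tensors = np.concatenate([encoding.tensors, recall.tensors])
    labels = np.concatenate([np.ones(len(encoding), dtype=int),
                             np.zeros(len(recall), dtype=int)])
    ids = [("enc", t) for t in encoding.trial_ids] + list(recall.trial_ids)
    groups = None
    if encoding.groups is not None and recall.groups is not None:
        groups = np.concatenate([encoding.groups, recall.groups])
    order = np.random.default_rng(seed).permutation(len(labels))
    ds = LabeledDataset(tensors[order], labels[order],
                        trial_ids=[ids[i] for i in order],
                        kind=TensorKind.STATE_SEGMENT, fs_hz=encoding.fs_hz,
                        provenance=encoding.provenance + recall.provenance,
                        groups=None if groups is None else groups[order])
    if not ds.is_trainable:
        raise ValueError("memory-state dataset must contain both classes")
    return ds


def smallest_mode(values) -> int:
    """Modal value; ties broken toward the smaller value."""
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    return int(vals[counts == counts.max()].min())


def extract_recall_epochs(schedule: TaskSchedule, recall_counts: np.ndarray,
                          rows: np.ndarray, fs_hz: float,
                          provenance: str = "") -> LabeledDataset:
    """One tensor per 30-s free-recall epoch, labeled good (1) when the
    number of recalled words strictly exceeds the mode of the per-session
    recall counts (smallest modal value on ties)."""
    if schedule.n_lists < 2:
        raise ValueError("need at least 2 recall epochs")
    counts = np.asarray(recall_counts, dtype=int)
    mode = smallest_mode(counts)
    labels = (counts > mode).astype(int)
    onsets = [on for on, _ in schedule.recall_windows]
    dur = schedule.recall_windows[0][1]
    tensors, kept = _cut_epochs(rows, fs_hz, onsets, dur)
    return LabeledDataset(tensors, labels[kept], trial_ids=list(kept),
                          kind=TensorKind.RECALL_EPOCH, fs_hz=fs_hz,
                          provenance=[provenance] if provenance else [])


def save_dataset(ds: LabeledDataset, out_dir, name: str = "dataset") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{name}.bin").write_bytes(ds.tensors.astype("<f4").tobytes())
    manifest = {
        "shape": list(ds.tensors.shape), "dtype": "float32",
        "byte_order": "little", "labels": ds.labels.tolist(),
        "trial_ids": [list(t) if isinstance(t, tuple) else t for t in ds.trial_ids],
        "kind": ds.kind, "fs_hz": ds.fs_hz, "row_names": ds.row_names,
        "provenance": ds.provenance,
        "groups": None if ds.groups is None else ds.groups.tolist(),
    }
    (out / f"{name}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_dataset(in_dir, name: str = "dataset") -> LabeledDataset:
    src = Path(in_dir)
    manifest = json.loads((src / f"{name}.json").read_text())
    tensors = np.frombuffer((src / f"{name}.bin").read_bytes(), dtype="<f4")
    tensors = tensors.reshape(manifest["shape"]).copy()
    groups = manifest.get("groups")
    return LabeledDataset(tensors, np.asarray(manifest["labels"]),
                          trial_ids=manifest["trial_ids"], kind=manifest["kind"],
                          fs_hz=manifest["fs_hz"], row_names=manifest["row_names"],
                          provenance=manifest["provenance"],
                          groups=None if groups is None else np.asarray(groups))
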