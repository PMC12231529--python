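"""Labeled, augmented training sequences and feature-set assembly.

Class labels come from the experiment protocol: five task epochs separated by
fatigue-inducing exercise, so epoch k carries tremor level k.  Window slicing
augments each labeled segment by cutting fixed-length sub-windows at random
offsets, and the four feature sets ablate the sensing modalities:

    set 1  EMG + ACC + CSAC   19 channels
    set 2  EMG + ACC          18 channels
    set 3  EMG + CSAC         17 channels
    set 4  ACC + CSAC          3 channels
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signalprep import (CANONICAL_ACC, CANONICAL_CSAC, CANONICAL_EMG_FA,
                         CANONICAL_EMG_UA, ProcessedChannels)

__all__ = [
    "FeatureSetSpec",
    "LabeledWindow",
    "label_by_epoch",
    "window_slice",
    "assemble_feature_set",
    "split_train_test",
    "stack_windows",
    "save_windows",
    "load_windows",
]

N_CLASSES = 5
DEFAULT_WINDOW_LENGTH = 1000
DEFAULT_N_WINDOWS = 50


@dataclass(frozen=True)
class FeatureSetSpec:
    """One modality combination for the ablation study."""

    set_id: int
    include_emg: bool
    include_acc: bool
    include_csac: bool

    _TABLE = {
        1: (True, True, True),
        2: (True, True, False),
        3: (True, False, True),
        4: (False, True, True),
    }

    @classmethod
    def from_id(cls, set_id: int) -> "FeatureSetSpec":
        if set_id not in cls._TABLE:
            raise ValueError(f"feature set id must be 1..4, got {set_id}")
        emg, acc, csac = cls._TABLE[set_id]
        return cls(set_id=set_id, include_emg=emg, include_acc=acc,
                   include_csac=csac)

    @property
    def channel_names(self) -> list[str]:
        names: list[str] = []
        if self.include_emg:
            names += CANONICAL_EMG_UA + CANONICAL_EMG_FA
        if self.include_acc:
            names += CANONICAL_ACC
        if self.include_csac:
            names += CANONICAL_CSAC
        if not names:
            raise ValueError("feature set selects no channels")
        return names

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class LabeledWindow:
    """One fixed-length training sequence with its tremor-level label."""

    data: np.ndarray       # (n_channels, window_length)
    label: int             # 1..5, the task-epoch number
    source_id: str         # participant/epoch provenance
    window_index: int


def label_by_epoch(channels: ProcessedChannels,
                   epoch_boundaries: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Cut the aligned record into the five task-epoch segments.

    ``epoch_boundaries`` holds six strictly increasing sample indices at the
    channels' rate.  Segment k (1-based) spans boundaries[k-1]:boundaries[k]
    and carries label k.  Returns ``[(label, data_slice), ...]``.
    """
    b = np.asarray(epoch_boundaries)
    if b.size != N_CLASSES + 1:
        raise ValueError(f"expected 6 epoch boundaries, got {b.size}")
    if np.any(np.diff(b) <= 0):
        raise ValueError("epoch boundaries must be strictly increasing")
    if b[-1] > channels.data.shape[1]:
        raise ValueError("epoch boundaries exceed the record length")
    return [(k + 1, channels.data[:, b[k]:b[k + 1]]) for k in range(N_CLASSES)]


def window_slice(segment: np.ndarray, label: int,
                 window_length: int = DEFAULT_WINDOW_LENGTH,
                 n_windows: int = DEFAULT_N_WINDOWS,
                 seed: int = 0,
                 source_id: str = "") -> list[LabeledWindow]:
    """Window-slicing augmentation of one labeled segment.

    Draws ``n_windows`` start offsets uniformly from the valid range and cuts
    windows of exactly ``window_length`` samples; every window inherits the
    segment's label.
    """
    segment = np.asarray(segment)
    length = segment.shape[-1]
    if length < window_length:
        raise ValueError(
            f"segment {source_id!r} has {length} samples, shorter than the "
            f"window length {window_length}")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, length - window_length + 1, size=n_windows)
    return [
        LabeledWindow(data=segment[..., o:o + window_length], label=int(label),
                      source_id=source_id, window_index=int(i))
        for i, o in enumerate(offsets)
    ]


def assemble_feature_set(channels: ProcessedChannels,
                         spec: FeatureSetSpec) -> ProcessedChannels:
    """Select the feature set's channels in canonical order."""
    return channels.select(spec.channel_names)


def split_train_test(windows: list[LabeledWindow],
                     test_fraction: float = 0.1,
                     seed: int = 0,
                     grouped: bool = False):
    """Stratified train/test split of labeled windows (default 9:1).

    With ``grouped`` set, all windows sharing a ``source_id`` land on the
    same side, preventing near-duplicate windows from leaking across the
    split; stratification is then over source segments per class.
    """
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[int]] = {}
    for i, w in enumerate(windows):
        by_label.setdefault(w.label, []).append(i)
    for label, idx in by_label.items():
        if len(idx) < 10:
            raise ValueError(f"class {label} has only {len(idx)} windows; "
                             "need at least 10 for a 9:1 split")

    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        if grouped:
            sources = sorted({windows[i].source_id for i in idx})
            sources = list(rng.permutation(sources))
            n_test = max(1, int(round(test_fraction * len(sources))))
            test_sources = set(sources[:n_test])
            for i in idx:
                (test_idx if windows[i].source_id in test_sources
                 else train_idx).append(int(i))
        else:
            perm = rng.permutation(idx)
            n_test = int(round(test_fraction * idx.size))
            test_idx.extend(int(i) for i in perm[:n_test])
            train_idx.extend(int(i) for i in perm[n_test:])
    train = [windows[i] for i in sorted(train_idx)]
    test = [windows[i] for i in sorted(test_idx)]
    return train, test


def stack_windows(windows: list[LabeledWindow]):
    """Stack windows into (X, y, source_ids) arrays for training."""
    X = np.stack([w.data for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows], dtype=np.int64)
    sources = np.array([w.source_id for w in windows])
    return X, y, sources


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_windows(windows: list[LabeledWindow], path,
                 channel_names: list[str],
                 manifest: dict | None = None) -> None:
    import h5py

    X, y, sources = stack_windows(windows)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X)
        f.create_dataset("y", data=y)
        f.create_dataset("source_id",
                         data=np.array([s.encode() for s in sources]))
        f.attrs["channel_names"] = [n.encode() for n in channel_names]
        for key, value in (manifest or {}).items():
            f.attrs[key] = value


def load_windows(path):
    import h5py

    with h5py.File(path, "r") as f:
        X = f["X"][()]
        y = f["y"][()]
        sources = [s.decode() for s in f["source_id"][()]]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["channel_names"]]
        manifest = {k: f.attrs[k] for k in f.attrs if k != "channel_names"}
    windows = [LabeledWindow(data=X[i], label=int(y[i]), source_id=sources[i],
                             window_index=i)
               for i in range(X.shape[0])]
    return windows, names, manifest
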