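import numpy as np
import pytest

import tremorstage as ts
from tremorstage import dataset as ds
from tremorstage import signalprep as sp


@pytest.fixture(scope="session")
def short_cfg() -> ts.SimulationConfig:
    """Small but fully structured cohort config for fast tests."""
    return ts.SimulationConfig(n_participants=2, epoch_duration_s=6.0, seed=7)


@pytest.fixture(scope="session")
def recording(short_cfg) -> ts.MultimodalRecording:
    return ts.simulate_recording(short_cfg, "P01")


@pytest.fixture(scope="session")
def channels(recording) -> sp.ProcessedChannels:
    return ts.preprocess_recording(recording)


@pytest.fixture(scope="session")
def boundaries_250(recording) -> np.ndarray:
    return sp.convert_boundaries(recording.epoch_boundaries,
                                 recording.fs_emg, sp.TARGET_FS)


@pytest.fixture(scope="session")
def window_builder():
    """Factory: simulate a cohort, preprocess, and slice labeled windows."""
    def build(n_participants, seed, window_length, n_windows):
        cfg = ts.SimulationConfig(n_participants=n_participants, seed=seed)
        windows = []
        for i in range(n_participants):
            pid = f"P{i + 1:02d}"
            rec = ts.simulate_recording(cfg, pid)
            channels = ts.preprocess_recording(rec)
            b = sp.convert_boundaries(rec.epoch_boundaries, rec.fs_emg,
                                      channels.fs)
            for label, seg in ds.label_by_epoch(channels, b):
                windows += ds.window_slice(
                    seg, label, window_length=window_length,
                    n_windows=n_windows, seed=seed + 97 * i + label,
                    source_id=f"{pid}/ep{label}")
        return windows
    return build


@pytest.fixture(scope="session")
def small_windows(channels, boundaries_250):
    """Feature-set-1 windows from one short recording (125 samples each)."""
    windows = []
    for label, seg in ds.label_by_epoch(channels, boundaries_250):
        windows += ds.window_slice(seg, label, window_length=125,
                                   n_windows=20, seed=100 + label,
                                   source_id=f"P01/ep{label}")
    return windows
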