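"""EMG / accelerometer preprocessing and multimodal alignment.

EMG path: DC-offset removal, second-order Butterworth band-stop around the
50 Hz power line, full-wave rectification and a linear envelope.  The
accelerometer path reduces each tri-axial stream to its signal magnitude
vector MMG_ACC = sqrt(ax^2 + ay^2 + az^2).  All channels — 500 Hz sensors and
the 50 fps camera-derived CSA feature — are then resampled onto one shared
250 Hz timeline and standardized to zero mean, unit variance per channel.

All filters are applied forward-backward (zero phase) so the modalities stay
temporally aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "ProcessedChannels",
    "remove_dc",
    "bandstop_powerline",
    "envelope",
    "acc_magnitude",
    "resample_align",
    "znormalize",
    "preprocess_recording",
    "convert_boundaries",
    "save_channels",
    "load_channels",
]

TARGET_FS = 250.0
POWERLINE_HZ = 50.0
NOTCH_HALF_WIDTH_HZ = 5.0   # 45-55 Hz stop band
ENVELOPE_CUTOFF_HZ = 6.0


@dataclass
class ProcessedChannels:
    """Aligned channels x time matrix at one sampling rate.

    ``provenance`` tags each channel with its pipeline of origin
    (``emg_envelope`` | ``mmg_acc`` | ``mmg_csac``); ``constant_flags`` marks
    channels that were constant before standardization (zeroed, not divided).
    """

    channel_names: list[str]
    data: np.ndarray                # (n_channels, n_samples)
    fs: float
    provenance: list[str]
    constant_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.provenance) != len(self.channel_names):
            raise ValueError("one provenance tag per channel required")
        if not self.constant_flags:
            self.constant_flags = [False] * len(self.channel_names)

    def select(self, names: list[str]) -> "ProcessedChannels":
        index = {n: i for i, n in enumerate(self.channel_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        rows = [index[n] for n in names]
        return ProcessedChannels(
            channel_names=list(names),
            data=self.data[rows],
            fs=self.fs,
            provenance=[self.provenance[i] for i in rows],
            constant_flags=[self.constant_flags[i] for i in rows],
        )


def remove_dc(x: np.ndarray) -> np.ndarray:
    """Subtract the per-channel mean (DC offset) over the recording."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return x - x.mean(axis=-1, keepdims=True)


def bandstop_powerline(x: np.ndarray, fs: float) -> np.ndarray:
    """Second-order Butterworth band-stop (45-55 Hz), zero phase."""
    if fs <= 110.0:
        raise ValueError(f"fs={fs} too low for a 50 Hz band-stop")
    sos = signal.butter(2,
                        [POWERLINE_HZ - NOTCH_HALF_WIDTH_HZ,
                         POWERLINE_HZ + NOTCH_HALF_WIDTH_HZ],
                        btype="bandstop", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def envelope(x: np.ndarray, fs: float,
             cutoff_hz: float = ENVELOPE_CUTOFF_HZ) -> np.ndarray:
    """Linear envelope: full-wave rectification + low-pass, clipped at zero."""
    sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(np.asarray(x, dtype=float)), axis=-1)
    return np.clip(env, 0.0, None)


def acc_magnitude(axes: np.ndarray) -> np.ndarray:
    """Signal magnitude vector of a (3, n) tri-axial accelerometer stream."""
    axes = np.asarray(axes, dtype=float)
    if axes.ndim != 2 or axes.shape[0] != 3:
        raise ValueError("expected a (3, n) array of axes")
    return np.sqrt(np.sum(axes**2, axis=0))


def _rational_rate(native_fs: float, target_fs: float) -> tuple[int, int]:
    from fractions import Fraction
    frac = Fraction(target_fs / native_fs).limit_denominator(1000)
    return frac.numerator, frac.denominator


def resample_align(streams: dict[str, tuple[np.ndarray, float, str]],
                   target_fs: float = TARGET_FS) -> ProcessedChannels:
    """Resample named 1-D streams onto a common timeline.

    ``streams`` maps channel name -> (series, native_fs, provenance_tag).
    Polyphase resampling provides anti-aliasing on decimation and band-limited
    interpolation on upsampling; channels are trimmed to the shortest
    resampled length (the overlapping span).
    """
    if not streams:
        raise ValueError("no streams given")
    resampled = {}
    for name, (series, fs, tag) in streams.items():
        if fs is None or fs <= 0:
            raise ValueError(f"stream {name!r} has unknown native rate")
        x = np.asarray(series, dtype=float)
        if fs == target_fs:
            resampled[name] = (x, tag)
            continue
        up, down = _rational_rate(fs, target_fs)
        resampled[name] = (signal.resample_poly(x, up, down), tag)
    n = min(x.size for x, _ in resampled.values())
    names = list(resampled)
    data = np.stack([resampled[name][0][:n] for name in names])
    return ProcessedChannels(
        channel_names=names,
        data=data,
        fs=target_fs,
        provenance=[resampled[name][1] for name in names],
    )


def znormalize(channels: ProcessedChannels,
               eps: float = 1e-12) -> ProcessedChannels:
    """Standardize each channel to zero mean, unit variance (population SD).

    Constant channels are mapped to zeros and flagged rather than divided.
    """
    data = channels.data
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)   # population (1/N) convention
    constant = sd[:, 0] < eps
    safe_sd = np.where(sd < eps, 1.0, sd)
    out = (data - mean) / safe_sd
    out[constant] = 0.0
    return ProcessedChannels(
        channel_names=list(channels.channel_names),
        data=out,
        fs=channels.fs,
        provenance=list(channels.provenance),
        constant_flags=list(constant),
    )


# ---------------------------------------------------------------------------
# full per-recording chain
# ---------------------------------------------------------------------------

CANONICAL_EMG_UA = [f"emg_ua{i}" for i in range(1, 9)]
CANONICAL_EMG_FA = [f"emg_fa{i}" for i in range(1, 9)]
CANONICAL_ACC = ["acc_ua", "acc_fa"]
CANONICAL_CSAC = ["csac"]
CANONICAL_ORDER = CANONICAL_EMG_UA + CANONICAL_EMG_FA + CANONICAL_ACC + CANONICAL_CSAC


def preprocess_recording(rec, csac: np.ndarray | None = None,
                         target_fs: float = TARGET_FS,
                         normalize: bool = True) -> ProcessedChannels:
    """Run the full preprocessing chain on a multimodal recording.

    EMG channels -> DC removal, 50 Hz band-stop, linear envelope; tri-axial
    accelerometers -> magnitude; CSA -> relative change vs the recorded rest
    area (or a caller-supplied MMG_CSAC series at the camera rate, e.g. the
    smoothed vision-pipeline output).  Everything is aligned at ``target_fs``
    and, by default, standardized per channel over the recording.
    """
    streams: dict[str, tuple[np.ndarray, float, str]] = {}
    for names, block in ((CANONICAL_EMG_UA, rec.emg_ua),
                         (CANONICAL_EMG_FA, rec.emg_fa)):
        clean = envelope(bandstop_powerline(remove_dc(block), rec.fs_emg),
                         rec.fs_emg)
        for i, name in enumerate(names):
            streams[name] = (clean[i], rec.fs_emg, "emg_envelope")
    streams["acc_ua"] = (acc_magnitude(rec.acc_ua), rec.fs_emg, "mmg_acc")
    streams["acc_fa"] = (acc_magnitude(rec.acc_fa), rec.fs_emg, "mmg_acc")
    if csac is None:
        from .csavision import relative_csa_change
        csac = relative_csa_change(rec.csa_area, rec.rest_area)
    streams["csac"] = (np.asarray(csac, dtype=float), rec.fs_cam, "mmg_csac")

    channels = resample_align(streams, target_fs=target_fs)
    channels = channels.select(CANONICAL_ORDER)
    return znormalize(channels) if normalize else channels


def convert_boundaries(boundaries: np.ndarray, fs_from: float,
                       fs_to: float) -> np.ndarray:
    """Map epoch-boundary sample indices between sampling rates."""
    b = np.asarray(boundaries)
    return np.round(b * (fs_to / fs_from)).astype(int)


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_channels(channels: ProcessedChannels, path,
                  epoch_boundaries: np.ndarray | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=channels.data)
        f.attrs["fs"] = channels.fs
        f.attrs["channel_names"] = [n.encode() for n in channels.channel_names]
        f.attrs["provenance"] = [p.encode() for p in channels.provenance]
        f.attrs["constant_flags"] = np.asarray(channels.constant_flags)
        if epoch_boundaries is not None:
            f.create_dataset("epoch_boundaries", data=np.asarray(epoch_boundaries))


def load_channels(path) -> tuple[ProcessedChannels, np.ndarray | None]:
    import h5py

    with h5py.File(path, "r") as f:
        channels = ProcessedChannels(
            channel_names=[n.decode() if isinstance(n, bytes) else str(n)
                           for n in f.attrs["channel_names"]],
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            provenance=[p.decode() if isinstance(p, bytes) else str(p)
                        for p in f.attrs["provenance"]],
            constant_flags=[bool(x) for x in f.attrs["constant_flags"]],
        )
        boundaries = f["epoch_boundaries"][()] if "epoch_boundaries" in f else None
    return channels, boundaries
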