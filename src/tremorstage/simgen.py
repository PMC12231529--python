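"""Synthetic multimodal fatigue-progression recordings.

Generates the five-level fatigue structure that fatigue-induced physiological
tremor (FIPT) studies report: as fatigue accumulates across task epochs, the
surface-EMG root-mean-square amplitude rises, the EMG median frequency falls,
an 8-14 Hz tremor component grows in the limb accelerometers, and the muscle
cross-sectional area (CSA) stays elevated relative to rest.

Each virtual participant yields one :class:`MultimodalRecording` with
8-channel upper-arm EMG, 8-channel forearm EMG, tri-axial accelerometers on
both segments (all at ``fs_emg``), and a forearm CSA series at the camera
rate.  :func:`simulate_marker_frames` renders the CSA series back into
per-frame fiducial-marker observations so the vision pipeline can be tested
end to end without real video.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal

__all__ = [
    "LevelProfile",
    "SimulationConfig",
    "MultimodalRecording",
    "default_profiles",
    "simulate_recording",
    "simulate_marker_frames",
    "median_frequency",
    "write_recording",
    "read_recording",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# profiles and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelProfile:
    """Target signal statistics for one tremor progression level (1..5).

    Parameters
    ----------
    level:
        Task-epoch number, 1 (rested) to 5 (maximally fatigued).
    emg_rms_gain:
        Dimensionless multiplier on the baseline EMG RMS amplitude.
    median_freq_hz:
        Target EMG median frequency in Hz; decreases with fatigue.
    tremor_amp_g:
        Peak amplitude of the tremor oscillation in the accelerometers (g).
    tremor_freq_hz:
        Tremor oscillation frequency (Hz); physiological tremor enhanced by
        fatigue sits in the 8-14 Hz band.
    csa_drift_frac:
        Mean relative CSA elevation over rest (fraction of the rest area).
    """

    level: int
    emg_rms_gain: float
    median_freq_hz: float
    tremor_amp_g: float
    tremor_freq_hz: float
    csa_drift_frac: float


def default_profiles() -> list[LevelProfile]:
    """Well-separated default level profiles.

    RMS gain rises linearly 1.0 -> 2.0 while the median frequency falls
    linearly 120 -> 80 Hz, the canonical myoelectric fatigue signature.
    Tremor amplitude grows 0 -> 0.05 g with the oscillation inside the
    8-14 Hz tremor band, and the CSA elevation grows 0 -> 8 % of rest.
    """
    gains = np.linspace(1.0, 2.0, 5)
    mdfs = np.linspace(120.0, 80.0, 5)
    amps = np.linspace(0.0, 0.05, 5)
    freqs = np.linspace(9.0, 13.0, 5)
    drifts = np.linspace(0.0, 0.08, 5)
    return [
        LevelProfile(
            level=i + 1,
            emg_rms_gain=float(gains[i]),
            median_freq_hz=float(mdfs[i]),
            tremor_amp_g=float(amps[i]),
            tremor_freq_hz=float(freqs[i]),
            csa_drift_frac=float(drifts[i]),
        )
        for i in range(5)
    ]


@dataclass
class SimulationConfig:
    """Configuration for one synthetic cohort.

    ``noise_sd`` is the baseline additive sensor noise: in g for the
    accelerometers and as a fraction of the rest area for the CSA channel.
    """

    n_participants: int = 20
    fs_emg: float = 500.0
    fs_cam: float = 50.0
    epoch_duration_s: float = 20.0
    profiles: list[LevelProfile] = field(default_factory=default_profiles)
    noise_sd: float = 0.01
    seed: int = 0
    emg_base_rms: float = 50.0          # microvolts at level 1 gain 1.0
    rest_area_cm2: float = 55.0         # typical adult forearm CSA
    csa_osc_freq_hz: float = 0.6        # slow contraction rhythm (36 bpm)
    csa_osc_frac: float = 0.01          # relative amplitude of that rhythm
    include_gravity: bool = False       # add a constant 1 g on the z axis

    def validate(self) -> None:
        if len(self.profiles) != 5:
            raise ConfigurationError(
                f"exactly 5 level profiles required, got {len(self.profiles)}"
            )
        levels = sorted(p.level for p in self.profiles)
        if levels != [1, 2, 3, 4, 5]:
            raise ConfigurationError(f"profile levels must be 1..5, got {levels}")
        prof = sorted(self.profiles, key=lambda p: p.level)
        gains = [p.emg_rms_gain for p in prof]
        mdfs = [p.median_freq_hz for p in prof]
        amps = [p.tremor_amp_g for p in prof]
        if any(b <= a for a, b in zip(gains, gains[1:])):
            raise ConfigurationError("emg_rms_gain must strictly increase with level")
        if any(b >= a for a, b in zip(mdfs, mdfs[1:])):
            raise ConfigurationError("median_freq_hz must strictly decrease with level")
        if any(b < a for a, b in zip(amps, amps[1:])):
            raise ConfigurationError("tremor_amp_g must be non-decreasing with level")
        for p in prof:
            if p.level >= 3 and not (8.0 <= p.tremor_freq_hz <= 14.0):
                raise ConfigurationError(
                    f"level {p.level} tremor_freq_hz={p.tremor_freq_hz} outside 8-14 Hz"
                )
        fmax = max(max(p.median_freq_hz, p.tremor_freq_hz) for p in prof)
        if self.fs_emg <= 2 * fmax:
            raise ConfigurationError(
                f"fs_emg={self.fs_emg} must exceed twice the highest target "
                f"frequency ({fmax} Hz)"
            )
        if self.rest_area_cm2 <= 0:
            raise ConfigurationError("rest_area_cm2 must be positive")


@dataclass
class MultimodalRecording:
    """Raw synchronized sensor streams for one participant.

    ``emg_ua``/``emg_fa`` are (8, n) arrays at ``fs_emg``; ``acc_ua``/``acc_fa``
    are (3, n) arrays at ``fs_emg``; ``csa_area`` is a (m,) array at ``fs_cam``
    in cm^2.  ``epoch_boundaries`` holds six sample indices (at ``fs_emg``)
    delimiting the five task epochs; epoch k spans
    ``boundaries[k-1]:boundaries[k]`` and carries class label k.
    """

    participant_id: str
    fs_emg: float
    fs_cam: float
    emg_ua: np.ndarray
    emg_fa: np.ndarray
    acc_ua: np.ndarray
    acc_fa: np.ndarray
    csa_area: np.ndarray
    epoch_boundaries: np.ndarray
    rest_area: float

    def __post_init__(self) -> None:
        n = self.emg_ua.shape[1]
        for name in ("emg_fa", "acc_ua", "acc_fa"):
            if getattr(self, name).shape[1] != n:
                raise ValueError(f"{name} length differs from emg_ua")
        b = np.asarray(self.epoch_boundaries)
        if np.any(np.diff(b) <= 0):
            raise ValueError("epoch_boundaries must be strictly increasing")
        if b[0] != 0 or b[-1] != n:
            raise ValueError("epoch_boundaries must cover the whole record")
        if not self.rest_area > 0:
            raise ValueError("rest_area must be positive")


# ---------------------------------------------------------------------------
# EMG carrier shaping
# ---------------------------------------------------------------------------

_BUTTER_ORDER = 4


def _mdf_of_cutoff(cutoff_hz: float, fs: float, order: int = _BUTTER_ORDER) -> float:
    """Median frequency of white noise shaped by a digital Butterworth low-pass."""
    b, a = signal.butter(order, cutoff_hz, fs=fs)
    w, h = signal.freqz(b, a, worN=4096, fs=fs)
    psd = np.abs(h) ** 2
    cum = np.cumsum(psd)
    half = cum[-1] / 2.0
    return float(np.interp(half, cum, w))

def _cutoff_for_mdf(target_mdf_hz: float, fs: float) -> float:
    """Invert :func:`_mdf_of_cutoff` for the shaping-filter cutoff."""
    nyq = fs / 2.0
    lo, hi = 1.0, nyq * 0.999
    f = lambda c: _mdf_of_cutoff(c, fs) - target_mdf_hz
    if f(hi) < 0:
        raise ConfigurationError(
            f"target median frequency {target_mdf_hz} Hz unreachable at fs={fs}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-3))


def _shaped_emg(rng: np.random.Generator, n: int, fs: float,
                target_mdf_hz: float, rms: float) -> np.ndarray:
    """Band-limited Gaussian EMG carrier with set median frequency and RMS."""
    cutoff = _cutoff_for_mdf(target_mdf_hz, fs)
    b, a = signal.butter(_BUTTER_ORDER, cutoff, fs=fs)
    x = signal.lfilter(b, a, rng.standard_normal(n))
    cur = np.sqrt(np.mean(x**2))
    if cur > 0:
        x *= rms / cur
    return x


# ---------------------------------------------------------------------------
# recording simulation
# ---------------------------------------------------------------------------

def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    # crc32 keeps the derived stream stable across sessions and platforms
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(participant_id.encode())])
    )


def simulate_recording(config: SimulationConfig,
                       participant_id: str) -> MultimodalRecording:
    """Simulate one participant's five-epoch multimodal recording.

    Deterministic given ``(config.seed, participant_id)``.  Per epoch the EMG
    channels are independent band-limited Gaussian carriers scaled to the
    profile's RMS gain and shaped to its median frequency; the accelerometers
    carry a tremor sinusoid of the profile's amplitude and frequency plus
    white noise; the CSA series is the rest area times
    ``1 + drift + slow contraction oscillation + noise``.
    """
    config.validate()
    rng = _participant_rng(config.seed, participant_id)
    prof = sorted(config.profiles, key=lambda p: p.level)

    n_ep = int(round(config.epoch_duration_s * config.fs_emg))
    m_ep = int(round(config.epoch_duration_s * config.fs_cam))
    n = 5 * n_ep

    emg_ua = np.empty((8, n))
    emg_fa = np.empty((8, n))
    acc_ua = np.zeros((3, n))
    acc_fa = np.zeros((3, n))
    csa = np.empty(5 * m_ep)

    # fixed tremor direction; upper arm oscillates less than the forearm
    direction = np.array([0.5, 0.5, np.sqrt(0.5)])
    t_emg = np.arange(n_ep) / config.fs_emg
    t_cam = np.arange(m_ep) / config.fs_cam

    for k, p in enumerate(prof):
        sl = slice(k * n_ep, (k + 1) * n_ep)
        rms = config.emg_base_rms * p.emg_rms_gain
        for ch in range(8):
            emg_ua[ch, sl] = _shaped_emg(rng, n_ep, config.fs_emg,
                                         p.median_freq_hz, rms)
        for ch in range(8):
            emg_fa[ch, sl] = _shaped_emg(rng, n_ep, config.fs_emg,
                                         p.median_freq_hz, rms)

        phase = rng.uniform(0, 2 * np.pi) if p.tremor_amp_g > 0 else 0.0
        tremor = np.sin(2 * np.pi * p.tremor_freq_hz * t_emg + phase)
        for ax in range(3):
            osc = p.tremor_amp_g * direction[ax] * tremor
            acc_fa[ax, sl] = osc
            acc_ua[ax, sl] = 0.6 * osc
            if config.noise_sd > 0:
                acc_fa[ax, sl] += rng.normal(0, config.noise_sd, n_ep)
                acc_ua[ax, sl] += rng.normal(0, config.noise_sd, n_ep)

        csl = slice(k * m_ep, (k + 1) * m_ep)
        rel = (p.csa_drift_frac
               + config.csa_osc_frac * np.sin(2 * np.pi * config.csa_osc_freq_hz
                                              * t_cam))
        if config.noise_sd > 0:
            rel = rel + rng.normal(0, config.noise_sd, m_ep)
        csa[csl] = config.rest_area_cm2 * (1.0 + rel)

    if config.include_gravity:
        acc_ua[2] += 1.0
        acc_fa[2] += 1.0

    boundaries = np.arange(6) * n_ep
    return MultimodalRecording(
        participant_id=participant_id,
        fs_emg=config.fs_emg,
        fs_cam=config.fs_cam,
        emg_ua=emg_ua,
        emg_fa=emg_fa,
        acc_ua=acc_ua,
        acc_fa=acc_fa,
        csa_area=csa,
        epoch_boundaries=boundaries,
        rest_area=config.rest_area_cm2,
    )


# ---------------------------------------------------------------------------
# fiducial-marker rendering of the CSA series
# ---------------------------------------------------------------------------

def simulate_marker_frames(recording: MultimodalRecording,
                           marker_edge_mm: float = 25.0,
                           scale_px_per_mm: float = 2.0,
                           jitter_px: float = 0.0,
                           seed: int = 0,
                           aspect_ratio: float = 0.8):
    """Render the CSA series as per-frame marker-centroid observations.

    Each camera view sees two square fiducial markers whose centroid
    separation encodes one ellipse axis of the forearm cross-section:
    the top view carries the major axis, the side view the minor axis
    (``minor = aspect_ratio * major``).  With ``jitter_px = 0`` the
    vision pipeline recovers ``recording.csa_area`` exactly.

    Returns ``(top_frames, side_frames)`` — two lists of
    :class:`tremorstage.csavision.MarkerFrame`.
    """
    from .csavision import MarkerFrame  # local import to avoid a cycle

    if scale_px_per_mm <= 0:
        raise ValueError("scale_px_per_mm must be positive")
    if not 0 < aspect_ratio <= 1:
        raise ValueError("aspect_ratio must be in (0, 1]")

    rng = np.random.default_rng(seed)
    area = np.asarray(recording.csa_area, dtype=float)
    # area = pi/4 * major * minor with minor = aspect * major
    major_cm = np.sqrt(4.0 * area / (np.pi * aspect_ratio))
    minor_cm = aspect_ratio * major_cm

    half_edge = marker_edge_mm * scale_px_per_mm / 2.0
    square = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) * half_edge

    def _view(axis_cm: np.ndarray, marker_id: int, anchor_xy) -> list:
        frames = []
        d_px = axis_cm * 10.0 * scale_px_per_mm
        for i, d in enumerate(d_px):
            for c0 in (np.array(anchor_xy, dtype=float),
                       np.array([anchor_xy[0] + d, anchor_xy[1]])):
                if jitter_px > 0:
                    c0 = c0 + rng.normal(0.0, jitter_px, 2)
                frames.append(MarkerFrame(
                    frame_index=i,
                    view="top" if marker_id == 0 else "side",
                    marker_id=marker_id,
                    centroid_px=(float(c0[0]), float(c0[1])),
                    corners_px=tuple(map(tuple, (square + c0))),
                ))
        return frames

    top = _view(major_cm, marker_id=0, anchor_xy=(150.0, 240.0))
    side = _view(minor_cm, marker_id=1, anchor_xy=(150.0, 240.0))
    return top, side


# ---------------------------------------------------------------------------
# validation statistic
# ---------------------------------------------------------------------------

def median_frequency(x: np.ndarray, fs: float) -> float:
    """Median frequency of a 1-D signal: the frequency splitting the power
    spectrum into two equal-power halves.

    Requires at least two seconds of samples for a usable spectral estimate.
    Raises ``ValueError`` on an all-zero signal, where the statistic is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("median_frequency expects a 1-D signal")
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of samples")
    if not np.any(x):
        raise ValueError("median frequency undefined for an all-zero signal")
    f, psd = signal.welch(x, fs=fs, nperseg=min(x.size, 1024))
    cum = np.cumsum(psd)
    return float(np.interp(cum[-1] / 2.0, cum, f))


# ---------------------------------------------------------------------------
# persistence: one CSV per stream + a sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: MultimodalRecording, out_dir: str | Path) -> Path:
    """Write one CSV per stream plus a JSON sidecar; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _frame(data: np.ndarray, prefix: str) -> pd.DataFrame:
        cols = {f"{prefix}{i + 1}": data[i] for i in range(data.shape[0])}
        df = pd.DataFrame(cols)
        df.insert(0, "sample", np.arange(data.shape[1]))
        return df

    _frame(rec.emg_ua, "emg_ua").to_csv(out / "emg_ua.csv", index=False)
    _frame(rec.emg_fa, "emg_fa").to_csv(out / "emg_fa.csv", index=False)
    acc_cols = ["ax", "ay", "az"]
    for name, data in (("acc_ua", rec.acc_ua), ("acc_fa", rec.acc_fa)):
        df = pd.DataFrame({c: data[i] for i, c in enumerate(acc_cols)})
        df.insert(0, "sample", np.arange(data.shape[1]))
        df.to_csv(out / f"{name}.csv", index=False)
    csa = pd.DataFrame({"sample": np.arange(rec.csa_area.size),
                        "area_cm2": rec.csa_area})
    csa.to_csv(out / "csa.csv", index=False)

    sidecar = {
        "participant_id": rec.participant_id,
        "fs_emg": rec.fs_emg,
        "fs_cam": rec.fs_cam,
        "epoch_boundaries": [int(b) for b in rec.epoch_boundaries],
        "rest_area": rec.rest_area,
    }
    (out / "recording.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_recording(in_dir: str | Path) -> MultimodalRecording:
    """Inverse of :func:`write_recording`."""
    d = Path(in_dir)
    meta = json.loads((d / "recording.json").read_text())

    def _load(name: str) -> np.ndarray:
        df = pd.read_csv(d / f"{name}.csv")
        return df.drop(columns="sample").to_numpy().T

    return MultimodalRecording(
        participant_id=meta["participant_id"],
        fs_emg=meta["fs_emg"],
        fs_cam=meta["fs_cam"],
        emg_ua=_load("emg_ua"),
        emg_fa=_load("emg_fa"),
        acc_ua=_load("acc_ua"),
        acc_fa=_load("acc_fa"),
        csa_area=pd.read_csv(d / "csa.csv")["area_cm2"].to_numpy(),
        epoch_boundaries=np.array(meta["epoch_boundaries"]),
        rest_area=meta["rest_area"],
    )
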