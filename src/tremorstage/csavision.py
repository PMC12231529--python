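"""Vision-based forearm cross-sectional-area (CSA) sensing.

The sensing idea: two square fiducial markers ride on an armband in each of
two orthogonal camera views.  The Euclidean distance between the marker
centroids in a view tracks one girth axis of the forearm; the known marker
edge length (25 mm) gives the pixel-to-metric scale.  Treating the top-view
distance as an ellipse's major axis and the side-view distance as the minor
axis, the ellipse area approximates the muscle cross-sectional area, and the
relative change of that area against the resting condition,

    MMG_CSAC(i) = (Area_i - Area_rest) / Area_rest,

is a mechanomyographic feature of muscle contraction and fatigue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter

__all__ = [
    "MarkerFrame",
    "ScaleCalibration",
    "CSASeries",
    "centroid_distance",
    "px_to_length",
    "ellipse_csa",
    "relative_csa_change",
    "smooth_csa",
    "detect_markers",
    "csa_from_marker_frames",
    "calibration_from_marker",
    "marker_frames_to_csv",
    "marker_frames_from_csv",
    "csa_series_to_csv",
]

IMAGE_WIDTH_PX = 640
IMAGE_HEIGHT_PX = 480


class UnsupportedOperation(RuntimeError):
    """A requested vision backend is not available in this installation."""


@dataclass(frozen=True)
class MarkerFrame:
    """One fiducial-marker observation in one camera frame.

    ``marker_id`` follows the rig convention: ID 0 markers appear in the top
    view, ID 1 markers in the side view.  Each view carries two physical
    markers per frame; pair membership is positional (emission order).
    """

    frame_index: int
    view: str                      # "top" | "side"
    marker_id: int
    centroid_px: tuple[float, float]
    corners_px: tuple[tuple[float, float], ...]

    def edge_lengths_px(self) -> np.ndarray:
        c = np.asarray(self.corners_px, dtype=float)
        return np.linalg.norm(np.roll(c, -1, axis=0) - c, axis=1)


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-metric scale for one camera view."""

    px_per_mm: float
    marker_edge_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")


def calibration_from_marker(frame: MarkerFrame,
                            marker_edge_mm: float = 25.0) -> ScaleCalibration:
    """Derive the view scale from the observed marker edge length."""
    edge_px = float(np.mean(frame.edge_lengths_px()))
    return ScaleCalibration(px_per_mm=edge_px / marker_edge_mm,
                            marker_edge_mm=marker_edge_mm)


@dataclass
class CSASeries:
    """Per-frame cross-sectional area (cm^2) and its relative change."""

    t: np.ndarray                  # frame timestamps, seconds
    area: np.ndarray               # cm^2
    rest_area: float               # cm^2
    relative_change: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.rest_area > 0:
            raise ValueError("rest_area must be positive")
        self.area = np.asarray(self.area, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        valid = self.area[np.isfinite(self.area)]
        if valid.size and np.any(valid <= 0):
            raise ValueError("areas must be positive")
        self.relative_change = relative_csa_change(self.area, self.rest_area)


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def centroid_distance(frame_a: MarkerFrame, frame_b: MarkerFrame) -> float:
    """Euclidean distance in pixels between two marker centroids.

    Both observations must come from the same view and frame.
    """
    if frame_a.view != frame_b.view:
        raise ValueError(f"view mismatch: {frame_a.view} vs {frame_b.view}")
    if frame_a.frame_index != frame_b.frame_index:
        raise ValueError("frame_index mismatch")
    a = np.asarray(frame_a.centroid_px, dtype=float)
    b = np.asarray(frame_b.centroid_px, dtype=float)
    return float(np.linalg.norm(a - b))


def px_to_length(d_px: float, cal: ScaleCalibration) -> float:
    """Convert a pixel distance to centimeters using the view calibration."""
    if d_px < 0:
        raise ValueError("distance must be non-negative")
    return float(d_px / cal.px_per_mm / 10.0)


def ellipse_csa(major_axis_cm: float, minor_axis_cm: float) -> float:
    """Ellipse-area approximation of the cross-section: pi * a/2 * b/2."""
    if major_axis_cm <= 0 or minor_axis_cm <= 0:
        raise ValueError("axes must be positive")
    return float(np.pi * (major_axis_cm / 2.0) * (minor_axis_cm / 2.0))


def relative_csa_change(area, rest_area: float) -> np.ndarray:
    """Relative area change against the resting condition, elementwise."""
    if rest_area <= 0:
        raise ValueError("rest_area must be positive")
    return (np.asarray(area, dtype=float) - rest_area) / rest_area


# ---------------------------------------------------------------------------
# smoothing with gap awareness
# ---------------------------------------------------------------------------

def _fill_short_gaps(x: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN runs of length <= max_gap.

    Returns the filled array and a boolean mask of frames still missing.
    """
    x = np.asarray(x, dtype=float).copy()
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return x, isnan
    # identify NaN runs
    idx = np.arange(x.size)
    still_missing = np.zeros(x.size, dtype=bool)
    run_start = None
    for i in range(x.size + 1):
        if i < x.size and isnan[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run = slice(run_start, i)
            length = i - run_start
            interior = run_start > 0 and i < x.size
            if length <= max_gap and interior:
                x[run] = np.interp(idx[run], [run_start - 1, i],
                                   [x[run_start - 1], x[i]])
            else:
                still_missing[run] = True
            run_start = None
    return x, still_missing


def smooth_csa(series: np.ndarray,
               median_window: int = 11,
               sg_order: int = 5,
               sg_window: int = 21,
               max_gap: int = 5) -> np.ndarray:
    """Outlier removal and smoothing of a CSA (or MMG_CSAC) series.

    A moving-median pass suppresses single-frame detection outliers, then a
    fifth-order Savitzky-Golay polynomial filter smooths environmental noise.
    NaN gaps up to ``max_gap`` frames are bridged by linear interpolation
    before filtering; longer gaps stay NaN in the output.
    """
    x = np.asarray(series, dtype=float)
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and exceed sg_order")
    if max(median_window, sg_window) > x.size:
        raise ValueError("filter window larger than the series")
    filled, missing = _fill_short_gaps(x, max_gap)
    med = ndimage.median_filter(filled, size=median_window, mode="nearest")
    out = savgol_filter(med, window_length=sg_window, polyorder=sg_order)
    out[missing] = np.nan
    return out


# ---------------------------------------------------------------------------
# marker detection backends
# ---------------------------------------------------------------------------

def _detect_threshold(image: np.ndarray) -> list[dict]:
    """Detect dark square blobs on a light background via thresholding.

    A deliberately simple backend sufficient for rendered or high-contrast
    footage: Otsu threshold, connected components, and a squareness test.
    Returns centroid and bounding-box corners per detection.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return []
    mask = img < threshold_otsu(img)
    detections = []
    for region in regionprops(label(mask)):
        h = region.bbox[2] - region.bbox[0]
        w = region.bbox[3] - region.bbox[1]
        if region.area < 25:
            continue
        if not (0.8 <= h / w <= 1.25):
            continue
        if region.extent < 0.85:       # filled square, not a ring or blob
            continue
        r0, c0, r1, c1 = region.bbox
        # bbox is exclusive on the high side; corner pixels at centers
        corners = ((c0 - 0.5, r0 - 0.5), (c1 - 0.5, r0 - 0.5),
                   (c1 - 0.5, r1 - 0.5), (c0 - 0.5, r1 - 0.5))
        cy, cx = region.centroid
        detections.append({"centroid": (cx, cy), "corners": corners})
    detections.sort(key=lambda d: d["centroid"][0])
    return detections


def detect_markers(image_sequence,
                   dictionary_id: int | None = None,
                   view: str = "top",
                   backend: str = "threshold",
                   n_expected: int = 2):
    """Detect square fiducial markers in an image sequence.

    Backends: ``"threshold"`` (built-in, intensity-based, suitable for
    rendered/high-contrast imagery; ``dictionary_id`` is ignored) and
    ``"aruco"`` (requires OpenCV at run time).  Frames where fewer than
    ``n_expected`` markers are found are flagged as missing, never fabricated.

    Returns ``(frames, missing_frame_indices)``.
    """
    if backend == "aruco":
        try:
            import cv2  # noqa: F401
        except ImportError as exc:
            raise UnsupportedOperation(
                "the 'aruco' backend requires OpenCV; install opencv-python "
                "or run the pipeline from centroid CSV tables"
            ) from exc
        raise UnsupportedOperation("aruco backend not wired in this build")
    if backend != "threshold":
        raise UnsupportedOperation(f"unknown vision backend {backend!r}")

    marker_id = 0 if view == "top" else 1
    frames: list[MarkerFrame] = []
    missing: list[int] = []
    for i, image in enumerate(image_sequence):
        dets = _detect_threshold(image)
        if len(dets) < n_expected:
            missing.append(i)
        for d in dets[:n_expected]:
            frames.append(MarkerFrame(
                frame_index=i, view=view, marker_id=marker_id,
                centroid_px=d["centroid"], corners_px=d["corners"]))
    return frames, missing


# ---------------------------------------------------------------------------
# pipeline: marker frames -> CSA series
# ---------------------------------------------------------------------------

def _distances_by_frame(frames: list[MarkerFrame]) -> dict[int, float]:
    by_frame: dict[int, list[MarkerFrame]] = {}
    for f in frames:
        by_frame.setdefault(f.frame_index, []).append(f)
    out = {}
    for idx, pair in by_frame.items():
        if len(pair) == 2:
            out[idx] = centroid_distance(pair[0], pair[1])
    return out


def csa_from_marker_frames(top_frames: list[MarkerFrame],
                           side_frames: list[MarkerFrame],
                           cal_top: ScaleCalibration,
                           cal_side: ScaleCalibration | None = None,
                           fs_cam: float = 50.0,
                           rest_window_s: float = 2.0,
                           rest_area: float | None = None,
                           sort_axes: bool = False) -> CSASeries:
    """Full sensing computation: centroid distances in two orthogonal views
    -> metric axis lengths -> ellipse area -> relative change vs rest.

    By convention the top-view distance is the major axis and the side-view
    distance the minor axis; set ``sort_axes`` to order them by magnitude
    instead.  ``rest_area`` defaults to the mean area over the first
    ``rest_window_s`` seconds.  Frames missing in either view yield NaN.
    """
    cal_side = cal_side or cal_top
    d_top = _distances_by_frame(top_frames)
    d_side = _distances_by_frame(side_frames)
    n = max(max(d_top, default=-1), max(d_side, default=-1)) + 1
    if n == 0:
        raise ValueError("no marker frames supplied")

    area = np.full(n, np.nan)
    for i in range(n):
        if i in d_top and i in d_side:
            a = px_to_length(d_top[i], cal_top)
            b = px_to_length(d_side[i], cal_side)
            if sort_axes and b > a:
                a, b = b, a
            area[i] = ellipse_csa(a, b)

    t = np.arange(n) / fs_cam
    if rest_area is None:
        n_rest = max(1, int(round(rest_window_s * fs_cam)))
        rest = area[:n_rest]
        rest = rest[np.isfinite(rest)]
        if rest.size == 0:
            raise ValueError("no valid frames in the rest window")
        rest_area = float(np.mean(rest))
    return CSASeries(t=t, area=area, rest_area=rest_area)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def marker_frames_to_csv(frames: list[MarkerFrame], path) -> None:
    rows = []
    for f in frames:
        row = {"frame": f.frame_index, "view": f.view, "marker_id": f.marker_id,
               "cx_px": f.centroid_px[0], "cy_px": f.centroid_px[1]}
        for j, (x, y) in enumerate(f.corners_px):
            row[f"x{j}_px"] = x
            row[f"y{j}_px"] = y
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def marker_frames_from_csv(path) -> list[MarkerFrame]:
    df = pd.read_csv(path)
    frames = []
    for _, r in df.iterrows():
        corners = tuple((float(r[f"x{j}_px"]), float(r[f"y{j}_px"]))
                        for j in range(4))
        frames.append(MarkerFrame(
            frame_index=int(r["frame"]), view=str(r["view"]),
            marker_id=int(r["marker_id"]),
            centroid_px=(float(r["cx_px"]), float(r["cy_px"])),
            corners_px=corners))
    return frames


def csa_series_to_csv(series: CSASeries, path) -> None:
    pd.DataFrame({
        "frame": np.arange(series.area.size),
        "t": series.t,
        "area_cm2": series.area,
        "mmg_csac": series.relative_change,
    }).to_csv(path, index=False)
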