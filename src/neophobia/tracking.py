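"""Offline centroid tracker: background subtraction and largest-blob centroid.

The tracker mirrors a standard single-animal pipeline: estimate a static
background as the per-pixel temporal median of a subsample of frames,
subtract each frame from it (signed, so only features *darker* than the
background survive), binarize, keep the largest connected component above a
minimum area, and take its intensity-free centroid.  Brief detection gaps
are bridged by linear interpolation and flagged; long gaps stay missing.
Pixel coordinates are finally calibrated to millimetres.

Coordinate convention: origin at the top-left of the reference image,
x rightward (columns), y downward (rows), continuous px.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, TrackingError
from .trajectory import Trajectory
from .video import FrameStack

DEFAULT_BLOB_LENGTH_MM = 3.29
DEFAULT_BLOB_ASPECT = 0.35


@dataclass(frozen=True)
class BackgroundModel:
    image: np.ndarray  # float, same shape as the frames
    method: str = "temporal_median"


@dataclass(frozen=True)
class Detection:
    frame_index: int
    x: float
    y: float
    area: int
    valid: bool

    @classmethod
    def invalid(cls, frame_index: int) -> "Detection":
        return cls(frame_index=frame_index, x=np.nan, y=np.nan, area=0, valid=False)


@dataclass(frozen=True)
class TrackingConfig:
    """Tracker settings.

    ``threshold=None`` selects Otsu's threshold on the pooled difference
    images of a frame subsample; ``min_area=None`` defaults to 25% of the
    expected blob area implied by ``blob_length_mm`` at ``px_per_mm``.
    """

    px_per_mm: float = 4.0
    threshold: float | None = None
    min_area: int | None = None
    gap_max: int = 5
    blob_length_mm: float = DEFAULT_BLOB_LENGTH_MM
    blob_aspect: float = DEFAULT_BLOB_ASPECT
    background_frames: int = 200

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ConfigurationError("px_per_mm must be positive")
        if self.threshold is not None and self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")
        if self.gap_max < 0:
            raise ConfigurationError("gap_max must be >= 0")

    def resolved_min_area(self) -> int:
        if self.min_area is not None:
            return int(self.min_area)
        a = self.blob_length_mm / 2.0 * self.px_per_mm
        b = a * self.blob_aspect
        return max(1, int(round(0.25 * np.pi * a * b)))


def estimate_background(frames: FrameStack, max_frames: int = 200) -> BackgroundModel:
    """Per-pixel temporal median over <= ``max_frames`` uniformly spaced frames.

    The median is robust to the moving animal as long as it occupies any
    given pixel in fewer than half of the sampled frames.
    """
    n = frames.n_frames
    if n < 2:
        raise ValueError("background estimation needs at least 2 frames")
    idx = np.unique(np.linspace(0, n - 1, min(n, max_frames)).astype(int))
    med = np.median(frames.frames[idx].astype(float), axis=0)
    return BackgroundModel(image=med)


def segment_frame(
    frame: np.ndarray,
    bg: BackgroundModel,
    threshold: float,
    min_area: int,
    frame_index: int = 0,
) -> Detection:
    """Centroid of the largest dark connected component, if any qualifies.

    The mask is ``(background - frame) > threshold``: only pixels darker
    than the background can belong to the subject, so bright artifacts are
    ignored by construction.
    """
    if threshold <= 0:
        raise ConfigurationError("binarization threshold must be positive")
    if frame.shape != bg.image.shape:
        raise ValueError("frame and background shapes differ")
    mask = (bg.image - frame.astype(float)) > threshold
    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        return Detection.invalid(frame_index)
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area:
        return Detection.invalid(frame_index)
    rows, cols = np.nonzero(labels == best)
    return Detection(
        frame_index=frame_index,
        x=float(cols.mean()),
        y=float(rows.mean()),
        area=int(areas[best - 1]),
        valid=True,
    )


def _auto_threshold(frames: FrameStack, bg: BackgroundModel, n_sample: int = 50) -> float:
    """Otsu's threshold on pooled difference images of a frame subsample."""
    idx = np.unique(np.linspace(0, frames.n_frames - 1, min(frames.n_frames, n_sample)).astype(int))
    diffs = bg.image[None, :, :] - frames.frames[idx].astype(float)
    diffs = np.clip(diffs, 0, None)
    if diffs.max() <= 1.0:  # nothing darker than background anywhere
        return 1.0
    return float(max(threshold_otsu(diffs), 1.0))


def _interpolate_gaps(
    x: np.ndarray, y: np.ndarray, gap_max: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bridge interior NaN runs of length <= gap_max linearly; flag them."""
    n = x.size
    interp = np.zeros(n, dtype=bool)
    xo, yo = x.copy(), y.copy()
    valid = ~np.isnan(x)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        if i > 0 and j < n and run <= gap_max:
            # chord between the flanking valid detections
            f = (np.arange(1, run + 1)) / (run + 1)
            xo[i:j] = x[i - 1] + f * (x[j] - x[i - 1])
            yo[i:j] = y[i - 1] + f * (y[j] - y[i - 1])
            interp[i:j] = True
        i = j
    return xo, yo, interp


def track(frames: FrameStack, cfg: TrackingConfig, subject_id: str = "track000") -> Trajectory:
    """Track one animal through a frame stack.

    Produces one record per frame; invalid detections inside gaps of at most
    ``cfg.gap_max`` frames are bridged by linear interpolation and flagged,
    longer gaps remain missing (NaN).  Raises :class:`TrackingError` when
    more than half of the frames yield no detection.
    """
    bg = estimate_background(frames, cfg.background_frames)
    thr = cfg.threshold if cfg.threshold is not None else _auto_threshold(frames, bg)
    min_area = cfg.resolved_min_area()

    n = frames.n_frames
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    for i in range(n):
        det = segment_frame(frames.frames[i], bg, thr, min_area, frame_index=i)
        if det.valid:
            x[i], y[i] = det.x, det.y
    n_invalid = int(np.isnan(x).sum())
    if n_invalid > 0.5 * n:
        raise TrackingError(
            f"tracking failed for {subject_id}: {n_invalid}/{n} frames without detection"
        )
    x, y, interp = _interpolate_gaps(x, y, cfg.gap_max)
    traj_px = Trajectory(
        subject_id=subject_id, x=x, y=y, fps=frames.fps, interpolated=interp, px_per_mm=1.0
    )
    return replace(
        traj_px,
        x=x / cfg.px_per_mm,
        y=y / cfg.px_per_mm,
        px_per_mm=cfg.px_per_mm,
    )


def calibrate(traj_px: Trajectory, arena_length_px: float, arena_length_mm: float) -> Trajectory:
    """Scale a pixel-space trajectory to mm using an arena landmark length."""
    if arena_length_px <= 0 or arena_length_mm <= 0:
        raise ConfigurationError("calibration lengths must be positive")
    px_per_mm = arena_length_px / arena_length_mm
    return replace(
        traj_px,
        x=traj_px.x / px_per_mm,
        y=traj_px.y / px_per_mm,
        px_per_mm=px_per_mm,
    )
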