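"""Render a trajectory into a synthetic overhead video.

The render is the tracker's end-to-end test bed: a dark elliptical blob (the
larva, default length 3.29 mm — the assay's mean body size) moves over a
light static background, optionally with the dark stimulus object drawn in
the stimulus sector.  Because the stimulus is part of the static background
it appears in every frame, so background subtraction must remove it — a
contract the tracking tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import ArenaConfig
from .errors import ConfigurationError
from .trajectory import Trajectory
from .video import FrameStack

STIMULUS_DIAMETER_MM = 7.0  # cone base diameter of the novel object
DEFAULT_BODY_LENGTH_MM = 3.29  # mean larva length in the assay


def stimulus_scale_percent(
    stimulus_diameter_mm: float = STIMULUS_DIAMETER_MM,
    body_length_mm: float = DEFAULT_BODY_LENGTH_MM,
) -> float:
    """Novel-object base diameter as a percentage of larval body length."""
    if stimulus_diameter_mm <= 0 or body_length_mm <= 0:
        raise ConfigurationError("lengths must be positive")
    return 100.0 * stimulus_diameter_mm / body_length_mm


@dataclass(frozen=True)
class RenderParams:
    px_per_mm: float = 4.0
    blob_length_mm: float = 3.29
    blob_aspect: float = 0.35  # width / length of the ellipse
    background_level: int = 220
    blob_level: int = 30
    noise_sd: float = 2.0  # additive gaussian, gray levels
    draw_stimulus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ConfigurationError("px_per_mm must be positive")
        if not (0 <= self.blob_level < self.background_level <= 255):
            raise ConfigurationError(
                "blob must be darker than the background (levels in 0..255)"
            )
        if self.blob_length_mm <= 0 or not (0 < self.blob_aspect <= 1):
            raise ConfigurationError("invalid blob geometry")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _frame_shape(arena: ArenaConfig, rp: RenderParams) -> tuple[int, int]:
    h = int(np.ceil(arena.width_mm * rp.px_per_mm))
    w = int(np.ceil(arena.length_mm * rp.px_per_mm))
    return h, w


def render_background(arena: ArenaConfig, rp: RenderParams) -> np.ndarray:
    """The clean static background (uint8), with the optional stimulus."""
    h, w = _frame_shape(arena, rp)
    bg = np.full((h, w), rp.background_level, dtype=np.uint8)
    if rp.draw_stimulus:
        cx, cy = arena.stimulus_center
        r = STIMULUS_DIAMETER_MM / 2.0 * rp.px_per_mm
        yy, xx = np.mgrid[0:h, 0:w]
        disk = (xx - cx * rp.px_per_mm) ** 2 + (yy - cy * rp.px_per_mm) ** 2 <= r**2
        bg[disk] = rp.blob_level
    return bg


def _stamp_blob(
    frame: np.ndarray, cx: float, cy: float, theta: float, a: float, b: float, level: int
) -> None:
    """Draw a filled ellipse (semi-axes a, b px, major axis at theta)."""
    h, w = frame.shape
    x0 = max(int(np.floor(cx - a)) - 1, 0)
    x1 = min(int(np.ceil(cx + a)) + 2, w)
    y0 = max(int(np.floor(cy - a)) - 1, 0)
    y1 = min(int(np.ceil(cy + a)) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    frame[y0:y1, x0:x1][(u / a) ** 2 + (v / b) ** 2 <= 1.0] = level


def render_video(traj: Trajectory, rp: RenderParams, arena: ArenaConfig | None = None) -> FrameStack:
    """Render one grayscale frame per trajectory point.

    The background (including the optional stimulus object) is identical in
    every frame; only the blob moves.  Additive gaussian noise with
    ``rp.noise_sd`` is drawn from a generator seeded by ``rp.seed``, so the
    stack is deterministic.
    """
    if arena is None:
        arena = traj.arena
    if arena is None:
        raise ConfigurationError("render_video needs an arena (traj.arena or argument)")
    a = rp.blob_length_mm / 2.0 * rp.px_per_mm
    b = a * rp.blob_aspect
    h, w = _frame_shape(arena, rp)
    if rp.blob_length_mm >= min(arena.length_mm, arena.width_mm):
        raise ConfigurationError("blob is larger than the arena")
    bg = render_background(arena, rp)
    rng = np.random.default_rng(rp.seed)

    xs = traj.x * rp.px_per_mm
    ys = traj.y * rp.px_per_mm
    # heading from consecutive positions; carry the last heading over pauses
    thetas = np.zeros(traj.n_frames)
    last = 0.0
    for i in range(traj.n_frames):
        j = min(i + 1, traj.n_frames - 1)
        dx, dy = xs[j] - xs[i], ys[j] - ys[i]
        if dx * dx + dy * dy > 1e-12:
            last = np.arctan2(dy, dx)
        thetas[i] = last

    frames = np.empty((traj.n_frames, h, w), dtype=np.uint8)
    for i in range(traj.n_frames):
        frame = bg.copy()
        if not np.isnan(xs[i]):
            _stamp_blob(frame, xs[i], ys[i], thetas[i], a, b, rp.blob_level)
        if rp.noise_sd > 0:
            noisy = frame + rng.normal(0.0, rp.noise_sd, frame.shape)
            frame = np.clip(noisy, 0, 255).astype(np.uint8)
        frames[i] = frame
    return FrameStack(frames=frames, fps=traj.fps)
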