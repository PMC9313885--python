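"""Per-frame centroid trajectories, the pipeline's central currency.

A trajectory holds one record per video frame: time stamp, calibrated x/y in
millimetres (NaN where the animal could not be located), and a flag marking
frames whose position was bridged by interpolation rather than detected.
Trajectories round-trip through a tab-delimited text format with columns
``subject_id, frame, t_s, x_mm, y_mm, interpolated``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .arena import ArenaConfig

_COLUMNS = ["subject_id", "frame", "t_s", "x_mm", "y_mm", "interpolated"]


@dataclass
class Trajectory:
    subject_id: str
    x: np.ndarray  # mm; NaN = missing
    y: np.ndarray
    fps: float
    interpolated: np.ndarray | None = None
    px_per_mm: float | None = None
    arena: "ArenaConfig | None" = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.interpolated is None:
            self.interpolated = np.zeros(self.x.shape, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
            if self.interpolated.shape != self.x.shape:
                raise ValueError("interpolated flag length mismatch")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.x.size

    @property
    def t(self) -> np.ndarray:
        """Time stamps in seconds, strictly increasing with step 1/fps."""
        return np.arange(self.n_frames) / self.fps

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.x) | np.isnan(self.y)

    def step_speeds(self, exclude_interpolated: bool = False) -> np.ndarray:
        """Instantaneous speed per step in mm/s (NaN where undefined).

        Step ``i`` spans frames ``i -> i+1`` and is attributed to its start
        frame.  Steps touching a missing frame are NaN; with
        ``exclude_interpolated`` steps touching a bridged frame are NaN too.
        """
        d = np.hypot(np.diff(self.x), np.diff(self.y)) * self.fps
        bad = self.missing
        if exclude_interpolated:
            bad = bad | self.interpolated
        d[bad[:-1] | bad[1:]] = np.nan
        return d

    # ------------------------------------------------------------------
    # text I/O
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "frame": np.arange(self.n_frames),
                "t_s": self.t,
                "x_mm": self.x,
                "y_mm": self.y,
                "interpolated": self.interpolated.astype(int),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _COLUMNS if c not in df.columns and c != "interpolated"]
        if missing:
            raise SchemaError(f"trajectory file {path} lacks columns {missing}")
        t = df["t_s"].to_numpy(dtype=float)
        if len(t) < 2:
            fps = 1.0
        else:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise SchemaError(f"trajectory file {path} has a non-uniform time base")
            fps = 1.0 / dt[0]
        interp = (
            df["interpolated"].to_numpy(dtype=bool)
            if "interpolated" in df.columns
            else None
        )
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            x=df["x_mm"].to_numpy(dtype=float),
            y=df["y_mm"].to_numpy(dtype=float),
            fps=fps,
            interpolated=interp,
        )

    def mirrored(self, arena: "ArenaConfig") -> "Trajectory":
        """Reflect the path across the arena's transverse midline."""
        return replace(self, x=arena.mirror_x(self.x), y=self.y.copy())
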