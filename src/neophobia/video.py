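"""Grayscale frame stacks and TIFF-stack I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml


@dataclass
class FrameStack:
    """An ordered stack of uniform 8-bit grayscale frames."""

    frames: np.ndarray  # (n_frames, height, width) uint8
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def write(self, path: str | Path, px_per_mm: float | None = None) -> None:
        """Write a multi-page TIFF plus a YAML sidecar with calibration."""
        path = Path(path)
        tifffile.imwrite(path, self.frames, photometric="minisblack")
        sidecar = {"fps": float(self.fps)}
        if px_per_mm is not None:
            sidecar["px_per_mm"] = float(px_per_mm)
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def read(cls, path: str | Path, fps: float | None = None) -> "FrameStack":
        path = Path(path)
        frames = tifffile.imread(path)
        if fps is None:
            sidecar = path.with_suffix(".yaml")
            if sidecar.exists():
                fps = float(yaml.safe_load(sidecar.read_text()).get("fps", 25.0))
            else:
                fps = 25.0
        return cls(frames=frames, fps=fps)


def read_sidecar(path: str | Path) -> dict:
    sidecar = Path(path).with_suffix(".yaml")
    return yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
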