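"""Arena geometry and choice-sector membership.

Two assay geometries are supported:

* ``two_circles`` — the novel-object test: a 7 x 5 cm rectangular tank with
  two 2-cm-diameter circular choice sectors, one centred in each half of the
  tank (the stimulus sector holds the object, the other is its mirror image
  and stays empty).
* ``three_thirds`` — the novel-odor test: a 15 x 5 cm tank split lengthwise
  into three equal sections; the end section on the stimulus side holds the
  odor source, the opposite end section is the control, and the middle third
  counts as neither.

Coordinates are in millimetres with the origin at the top-left corner of the
arena, x increasing rightward along the length and y downward across the
width (image convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, GeometryError

# Per-frame sector codes.
NEITHER = 0
STIMULUS = 1
EMPTY = 2  # empty circle (object test) or control end-section (odor test)
MISSING = -1

#: Default arena footprints (mm): object test 70 x 50, odor test 150 x 50.
OBJECT_ARENA_MM = (70.0, 50.0)
ODOR_ARENA_MM = (150.0, 50.0)
SECTOR_DIAMETER_MM = 20.0


@dataclass(frozen=True)
class ArenaConfig:
    """Rectangular arena with two-choice sector geometry.

    Parameters
    ----------
    length_mm, width_mm:
        Inner footprint of the tank.
    mode:
        ``"two_circles"`` or ``"three_thirds"``.
    stimulus_side:
        Which end of the length axis carries the stimulus (``"left"`` means
        small x). Counterbalancing metadata only: every downstream metric is
        expressed in stimulus/empty terms, never left/right.
    sector_diameter_mm:
        Diameter of the circular choice sectors (two_circles mode only).
    """

    length_mm: float = OBJECT_ARENA_MM[0]
    width_mm: float = OBJECT_ARENA_MM[1]
    mode: str = "two_circles"
    stimulus_side: str = "left"
    sector_diameter_mm: float = SECTOR_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ConfigurationError("arena dimensions must be positive")
        if self.mode not in ("two_circles", "three_thirds"):
            raise ConfigurationError(f"unknown arena mode: {self.mode!r}")
        if self.stimulus_side not in ("left", "right"):
            raise ConfigurationError(
                f"stimulus_side must be 'left' or 'right', got {self.stimulus_side!r}"
            )
        if self.mode == "two_circles":
            r = self.sector_diameter_mm / 2.0
            if r <= 0:
                raise ConfigurationError("sector diameter must be positive")
            cx, cy = self.stimulus_center
            # circles sit at the centre of each half; they must fit inside
            if cx - r < 0 or cx + r > self.length_mm or cy - r < 0 or cy + r > self.width_mm:
                raise ConfigurationError(
                    "choice circles do not fit inside the arena rectangle"
                )

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    @property
    def radius_mm(self) -> float:
        return self.sector_diameter_mm / 2.0

    @property
    def _half_centers(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Centres of the left and right halves of the tank."""
        y = self.width_mm / 2.0
        return (self.length_mm / 4.0, y), (3.0 * self.length_mm / 4.0, y)

    @property
    def stimulus_center(self) -> tuple[float, float]:
        left, right = self._half_centers
        return left if self.stimulus_side == "left" else right

    @property
    def empty_center(self) -> tuple[float, float]:
        """Mirror position of the stimulus sector about the arena midline."""
        left, right = self._half_centers
        return right if self.stimulus_side == "left" else left

    @property
    def third_edges(self) -> tuple[float, float]:
        """x positions of the two boundaries between longitudinal thirds."""
        return self.length_mm / 3.0, 2.0 * self.length_mm / 3.0

    def mirror_x(self, x: np.ndarray) -> np.ndarray:
        """Reflect x coordinates across the arena's transverse midline."""
        return self.length_mm - np.asarray(x, dtype=float)

    # ------------------------------------------------------------------
    # sector membership
    # ------------------------------------------------------------------
    def sector_labels(self, x, y) -> np.ndarray:
        """Label positions as STIMULUS / EMPTY / NEITHER (MISSING for NaN).

        Circle membership is boundary-inclusive (distance <= radius).  The
        longitudinal thirds are half-open intervals [start, end) except the
        final third, which is closed, so the three sections partition the
        length exactly.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have matching shapes")
        ok = ~(np.isnan(x) | np.isnan(y))
        eps = 1e-9
        if np.any(
            (x[ok] < -eps)
            | (x[ok] > self.length_mm + eps)
            | (y[ok] < -eps)
            | (y[ok] > self.width_mm + eps)
        ):
            raise GeometryError("trajectory positions fall outside the arena")

        labels = np.full(x.shape, NEITHER, dtype=np.int8)
        if self.mode == "two_circles":
            r2 = self.radius_mm**2
            for code, (cx, cy) in (
                (STIMULUS, self.stimulus_center),
                (EMPTY, self.empty_center),
            ):
                inside = (x - cx) ** 2 + (y - cy) ** 2 <= r2
                labels[ok & inside] = code
        else:
            lo, hi = self.third_edges
            left_third = x < lo
            right_third = x >= hi
            if self.stimulus_side == "left":
                stim, ctrl = left_third, right_third
            else:
                stim, ctrl = right_third, left_third
            labels[ok & stim] = STIMULUS
            labels[ok & ctrl] = EMPTY
        labels[~ok] = MISSING
        return labels


def object_arena(stimulus_side: str = "left") -> ArenaConfig:
    """The novel-object test arena: 70 x 50 mm, two 20-mm circles."""
    return ArenaConfig(*OBJECT_ARENA_MM, mode="two_circles", stimulus_side=stimulus_side)


def odor_arena(stimulus_side: str = "left") -> ArenaConfig:
    """The novel-odor test arena: 150 x 50 mm, three longitudinal thirds."""
    return ArenaConfig(*ODOR_ARENA_MM, mode="three_thirds", stimulus_side=stimulus_side)
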