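"""Ground-truthed synthetic larva trajectories and designed cohorts.

The movement model is a two-state (move/pause) correlated random walk.  While
moving, the heading receives a wrapped-normal perturbation whose
concentration is set by ``heading_persistence`` plus a deterministic bias
``|attraction| * sin(bearing_to_target - heading)``.  Positive attraction
steers the walker toward the centre of the stimulus sector; negative
attraction (avoidance) steers it toward the mirror-image empty sector — a
retreat to the far side of the tank, which is how stimulus avoidance
manifests in the assay — so the expected preference rises monotonically
through 50% as the coefficient crosses zero.  Step lengths are gamma-distributed with mean
``mean_speed / fps``; inside the stimulus sector the mean step is scaled by
``stimulus_speed_factor`` so per-sector velocity differences are a
recoverable signal.  Walls are reflective.  Pauses repeat the previous
position; the move/pause switch is a two-state Markov chain with per-step
probabilities ``p_pause`` (move→pause) and ``p_resume`` (pause→move), started
from its stationary distribution.

Subjects are not interchangeable: each walker carries a thigmotaxis trait, a
wall-ward heading bias drawn per subject from a gamma distribution
(``wall_bias_mean``, ``wall_bias_shape``).  Strongly wall-bound larvae rarely
enter the interior choice sectors, so choice-sector totals vary widely and
persistently across subjects — the regime that motivates weighting the
preference analysis by those totals — while weakly wall-bound larvae sample
the sectors often.  Everything is deterministic given the seed, and cohorts
with per-cell attraction structure reproduce the assay's 2-treatment x 3-age
design (n subjects per cell) for power and type-I-error studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .arena import ArenaConfig
from .errors import ConfigurationError
from .trajectory import Trajectory


@dataclass(frozen=True)
class SimParams:
    """Generative settings for a single simulated trial.

    Defaults describe a 10-min novel-object trial in the 70 x 50 mm arena:
    25 fps video, 8 mm/s mean cruising speed (about 2.4 body lengths/s for a
    3.3-mm larva), strongly persistent headings (decorrelation time ~2 s,
    the straight-swimming regime of cruising larvae), pause bouts occupying
    roughly one sixth of the trial, and a thigmotaxis trait distribution
    whose scale reproduces the wide between-subject spread of choice-sector
    totals the assay reports.
    """

    arena_length_mm: float = 70.0
    arena_width_mm: float = 50.0
    fps: float = 25.0
    duration_s: float = 600.0
    mean_speed_mms: float = 8.0
    speed_shape: float = 2.0  # gamma shape of step lengths
    heading_persistence: float = 0.98  # wrapped-normal mean resultant length
    attraction: float = 0.0  # signed heading bias toward stimulus centre
    stimulus_speed_factor: float = 1.0  # mean-step multiplier inside stimulus
    p_pause: float = 0.02
    p_resume: float = 0.10
    wall_bias_mean: float = 0.05  # mean of the per-subject thigmotaxis trait
    wall_bias_shape: float = 2.0  # gamma shape of the trait distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_length_mm <= 0 or self.arena_width_mm <= 0:
            raise ConfigurationError("arena dimensions must be positive")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fps and duration must be positive")
        if not (0.0 <= self.heading_persistence < 1.0):
            raise ConfigurationError("heading_persistence must lie in [0, 1)")
        for name in ("p_pause", "p_resume"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.mean_speed_mms < 0 or self.speed_shape <= 0:
            raise ConfigurationError("speeds must be >= 0 and speed_shape > 0")
        if self.stimulus_speed_factor <= 0:
            raise ConfigurationError("stimulus_speed_factor must be positive")
        if self.wall_bias_mean < 0 or self.wall_bias_shape <= 0:
            raise ConfigurationError("wall bias mean must be >= 0 and shape > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def turn_sd(self) -> float:
        """Wrapped-normal sd giving mean resultant = heading_persistence."""
        if self.heading_persistence == 0.0:
            return np.pi  # effectively uniform turning
        return float(np.sqrt(-2.0 * np.log(self.heading_persistence)))


@dataclass(frozen=True)
class CohortDesign:
    """Factorial cohort layout: treatments x ages with per-cell effects.

    ``attraction_by_cell`` maps ``(treatment, age)`` to the attraction
    coefficient used for every subject of that cell; every cell must be
    covered.  ``speed_factor_by_cell`` optionally does the same for the
    in-stimulus speed multiplier (default 1 everywhere).
    """

    n_per_cell: int = 20
    treatments: tuple[str, ...] = ("enrichment", "no_enrichment")
    ages_dpf: tuple[int, ...] = (7, 14, 21)
    attraction_by_cell: dict = field(default_factory=dict)
    speed_factor_by_cell: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ConfigurationError("n_per_cell must be >= 1")
        for cell in self.cells:
            if cell not in self.attraction_by_cell:
                raise ConfigurationError(f"attraction undefined for cell {cell}")

    @property
    def cells(self) -> list[tuple[str, int]]:
        return [(t, a) for t in self.treatments for a in self.ages_dpf]


def _check_arena(params: SimParams, arena: ArenaConfig) -> None:
    if (
        abs(arena.length_mm - params.arena_length_mm) > 1e-9
        or abs(arena.width_mm - params.arena_width_mm) > 1e-9
    ):
        raise ConfigurationError(
            "arena geometry does not match the simulation parameters "
            f"({arena.length_mm} x {arena.width_mm} vs "
            f"{params.arena_length_mm} x {params.arena_width_mm} mm)"
        )


def _simulate_paths(
    n: int,
    params: SimParams,
    arena: ArenaConfig,
    rng: np.random.Generator,
    attraction: np.ndarray | None = None,
    speed_factor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``n`` independent walkers in lockstep.

    Returns position arrays of shape (n, n_frames).  ``attraction`` and
    ``speed_factor`` may vary per walker, which lets a whole cohort (or a
    replicate grid) share one vectorised pass.
    """
    _check_arena(params, arena)
    n_frames = params.n_frames
    L, W = params.arena_length_mm, params.arena_width_mm
    beta = np.full(n, params.attraction) if attraction is None else np.asarray(attraction, float)
    sfac = (
        np.full(n, params.stimulus_speed_factor)
        if speed_factor is None
        else np.asarray(speed_factor, float)
    )
    lo, hi = arena.third_edges
    stim_left = arena.stimulus_side == "left"
    if arena.mode == "two_circles":
        cx, cy = arena.stimulus_center
        ex, ey = arena.empty_center
        r2 = arena.radius_mm**2
    else:  # attractors = centres of the two end-thirds
        cx = L / 6.0 if stim_left else 5.0 * L / 6.0
        cy = W / 2.0
        ex, ey = L - cx, cy
        r2 = None

    mean_step = params.mean_speed_mms / params.fps
    shape = params.speed_shape
    sd = params.turn_sd

    # per-subject thigmotaxis trait and per-walker RNG seeds come from the
    # master generator, so every output bit is a pure function of its seed
    if params.wall_bias_mean > 0:
        kappa = rng.gamma(
            params.wall_bias_shape, params.wall_bias_mean / params.wall_bias_shape, n
        )
    else:
        kappa = np.zeros(n)
    seeds = rng.integers(0, 2**31 - 1, n)

    denom = params.p_pause + params.p_resume
    p_moving0 = params.p_resume / denom if denom > 0 else 1.0

    x = np.empty((n, n_frames))
    y = np.empty((n, n_frames))
    _walk_kernel(
        x,
        y,
        seeds,
        beta,
        sfac,
        kappa,
        params.p_pause,
        params.p_resume,
        p_moving0,
        sd,
        shape,
        mean_step / shape,
        L,
        W,
        cx,
        cy,
        ex,
        ey,
        -1.0 if r2 is None else r2,
        lo,
        hi,
        stim_left,
    )
    return x, y


@numba.njit(cache=True)
def _walk_kernel(
    x,
    y,
    seeds,
    beta,
    sfac,
    kappa,
    p_pause,
    p_resume,
    p_moving0,
    turn_sd,
    gamma_shape,
    gamma_scale,
    L,
    W,
    cx,
    cy,
    ex,
    ey,
    r2,
    third_lo,
    third_hi,
    stim_left,
):  # pragma: no cover - exercised via _simulate_paths
    n, n_frames = x.shape
    half_L = 0.5 * L
    half_W = 0.5 * W
    step_cap = 0.45 * min(L, W)
    for j in range(n):
        np.random.seed(seeds[j])
        px = np.random.random() * L
        py = np.random.random() * W
        th = (np.random.random() * 2.0 - 1.0) * np.pi
        mov = np.random.random() < p_moving0
        bj = beta[j]
        sj = sfac[j]
        kj = kappa[j]
        x[j, 0] = px
        y[j, 0] = py
        for i in range(1, n_frames):
            u = np.random.random()
            mov = (u >= p_pause) if mov else (u < p_resume)

            if bj != 0.0 or sj != 1.0:
                if r2 >= 0.0:
                    dxs = px - cx
                    dys = py - cy
                    in_stim = dxs * dxs + dys * dys <= r2
                else:
                    in_stim = (px < third_lo) if stim_left else (px >= third_hi)
            else:
                in_stim = False

            if bj != 0.0 or kj != 0.0:
                # heading bias via sin(bearing - th) = sin(b)cos(th) - cos(b)sin(th)
                ct = np.cos(th)
                st = np.sin(th)
                bias = 0.0
                if bj != 0.0:
                    # avoidance = retreat toward the opposite (empty) sector
                    if bj > 0.0:
                        dx = cx - px
                        dy = cy - py
                    else:
                        dx = ex - px
                        dy = ey - py
                    r = np.sqrt(dx * dx + dy * dy)
                    if r > 1e-12:
                        bias += abs(bj) * (dy * ct - dx * st) / r
                if kj != 0.0:
                    dx = px - half_L
                    dy = py - half_W
                    r = np.sqrt(dx * dx + dy * dy)
                    if r > 1e-12:
                        bias += kj * (dy * ct - dx * st) / r
                th += bias
            th += np.random.normal(0.0, turn_sd)

            if mov:
                if gamma_shape == 2.0:
                    # Gamma(2, scale) as the sum of two exponentials
                    u1 = np.random.random()
                    u2 = np.random.random()
                    prod = u1 * u2
                    step = -np.log(prod) * gamma_scale if prod > 0.0 else step_cap
                else:
                    step = np.random.gamma(gamma_shape, gamma_scale)
                if step > step_cap:
                    step = step_cap
                if in_stim and sj != 1.0:
                    step *= sj
                ct = np.cos(th)
                st = np.sin(th)
                nx = px + step * ct
                ny = py + step * st
                # reflective walls (steps are capped well below arena size)
                flipped = False
                if nx < 0.0:
                    nx = -nx
                    ct = -ct
                    flipped = True
                elif nx > L:
                    nx = 2.0 * L - nx
                    ct = -ct
                    flipped = True
                if ny < 0.0:
                    ny = -ny
                    st = -st
                    flipped = True
                elif ny > W:
                    ny = 2.0 * W - ny
                    st = -st
                    flipped = True
                if flipped:
                    th = np.arctan2(st, ct)
                if nx < 0.0:
                    nx = 0.0
                elif nx > L:
                    nx = L
                if ny < 0.0:
                    ny = 0.0
                elif ny > W:
                    ny = W
                px = nx
                py = ny
            x[j, i] = px
            y[j, i] = py


def simulate_trajectory(
    params: SimParams,
    arena: ArenaConfig | None = None,
    subject_id: str = "sim000",
) -> Trajectory:
    """Simulate one larva trial; deterministic given ``params.seed``."""
    if arena is None:
        arena = ArenaConfig(params.arena_length_mm, params.arena_width_mm)
    rng = np.random.default_rng(params.seed)
    x, y = _simulate_paths(1, params, arena, rng)
    return Trajectory(subject_id=subject_id, x=x[0], y=y[0], fps=params.fps, arena=arena)


def make_cohort(
    design: CohortDesign,
    params: SimParams,
    arena: ArenaConfig | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate one trajectory per subject of a factorial cohort.

    Returns the trajectories and a design table with columns
    ``subject_id, treatment, age_dpf, attraction``.  All subjects are run in
    one vectorised pass; the stream is seeded from ``design.seed`` so a
    cohort is reproducible bit-for-bit.
    """
    if arena is None:
        arena = ArenaConfig(params.arena_length_mm, params.arena_width_mm)
    cells = design.cells
    n_total = design.n_per_cell * len(cells)
    beta = np.empty(n_total)
    sfac = np.empty(n_total)
    rows = []
    k = 0
    for treatment, age in cells:
        for j in range(design.n_per_cell):
            beta[k] = design.attraction_by_cell[(treatment, age)]
            sfac[k] = (
                design.speed_factor_by_cell.get((treatment, age), 1.0)
                if design.speed_factor_by_cell
                else params.stimulus_speed_factor
            )
            rows.append(
                {
                    "subject_id": f"s{k:03d}",
                    "treatment": treatment,
                    "age_dpf": age,
                    "attraction": beta[k],
                }
            )
            k += 1
    rng = np.random.default_rng(design.seed)
    x, y = _simulate_paths(n_total, params, arena, rng, attraction=beta, speed_factor=sfac)
    trajs = [
        Trajectory(subject_id=rows[i]["subject_id"], x=x[i], y=y[i], fps=params.fps, arena=arena)
        for i in range(n_total)
    ]
    return trajs, pd.DataFrame(rows)
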