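"""Behavioral endpoints of the two-choice assay.

A trajectory becomes a row of per-subject endpoints: time in each choice
sector, approach (entry) counts, mean swimming velocity per sector, the
fraction of the trial spent moving, and the exclusion flags the assay
prescribes — subjects moving less than 5% of the trial are discarded in the
object test (immobility, a health proxy), and subjects spending less than 5%
of the trial in the two end sections are discarded in the odor test
(nonchoosers).  Included subjects yield preference indices: time (or
approaches) toward the stimulus as a percentage of time (or approaches)
toward both sectors, with the corresponding totals kept as analysis weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .arena import EMPTY, MISSING, STIMULUS, ArenaConfig
from .errors import UndefinedPreferenceError
from .trajectory import Trajectory

DEFAULT_MIN_DWELL = 2  # frames; debounces boundary jitter
DEFAULT_SPEED_FLOOR = 1.0  # mm/s; "moving" for the activity fraction
EXCLUSION_FRACTION = 0.05  # the assay's 5% discard rules


@dataclass(frozen=True)
class TrialMetrics:
    subject_id: str
    t_stimulus: float  # s
    t_empty: float  # s
    n_approach_stimulus: int
    n_approach_empty: int
    v_stimulus: float  # mm/s; NaN when no within-sector step exists
    v_empty: float
    activity_fraction: float
    test_duration: float  # s
    included: bool = True
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class PreferenceRecord:
    percent_time: float  # %
    percent_approach: float
    weight_time: float  # s spent in both sectors
    weight_approach: float  # total approaches to both sectors


def assign_sectors(traj: Trajectory, arena: ArenaConfig) -> np.ndarray:
    """Per-frame sector labels (STIMULUS / EMPTY / NEITHER, MISSING for NaN)."""
    return arena.sector_labels(traj.x, traj.y)


def time_in_sector(labels: np.ndarray, fps: float) -> tuple[float, float]:
    """Occupancy time per choice sector; each labeled frame adds 1/fps s."""
    labels = np.asarray(labels)
    return (
        float(np.count_nonzero(labels == STIMULUS) / fps),
        float(np.count_nonzero(labels == EMPTY) / fps),
    )


def _count_runs(inside: np.ndarray, min_dwell: int) -> int:
    """Number of maximal True-runs of length >= min_dwell."""
    inside = np.asarray(inside, dtype=bool)
    if inside.size == 0:
        return 0
    padded = np.concatenate(([False], inside, [False])).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return int(np.count_nonzero(ends - starts >= min_dwell))


def count_approaches(labels: np.ndarray, min_dwell: int = DEFAULT_MIN_DWELL) -> tuple[int, int]:
    """Approach = an entry into a sector persisting >= ``min_dwell`` frames.

    Equivalently the number of maximal inside-runs of that length, so an
    entry and the occupancy bout it opens always agree.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    labels = np.asarray(labels)
    return (
        _count_runs(labels == STIMULUS, min_dwell),
        _count_runs(labels == EMPTY, min_dwell),
    )


def sector_velocity(traj: Trajectory, labels: np.ndarray) -> tuple[float, float]:
    """Mean speed (mm/s) over steps starting inside each sector.

    A step spanning a boundary belongs to the sector of its start frame.
    Interpolated and missing frames contribute no steps.  NaN when a sector
    has no step at all (undefined, never fabricated).
    """
    speeds = traj.step_speeds(exclude_interpolated=True)
    start = np.asarray(labels)[:-1]
    out = []
    for code in (STIMULUS, EMPTY):
        sel = speeds[(start == code) & ~np.isnan(speeds)]
        out.append(float(sel.mean()) if sel.size else float("nan"))
    return out[0], out[1]


def activity_fraction(traj: Trajectory, speed_floor: float = DEFAULT_SPEED_FLOOR) -> float:
    """Fraction of observed steps faster than ``speed_floor`` (time moving /
    total testing time)."""
    speeds = traj.step_speeds()
    ok = ~np.isnan(speeds)
    if not ok.any():
        return 0.0
    return float(np.count_nonzero(speeds[ok] > speed_floor) / np.count_nonzero(ok))


def compute_trial_metrics(
    traj: Trajectory,
    arena: ArenaConfig,
    min_dwell: int = DEFAULT_MIN_DWELL,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
) -> TrialMetrics:
    """All endpoints for one subject (inclusion flags not yet applied)."""
    labels = assign_sectors(traj, arena)
    t_s, t_e = time_in_sector(labels, traj.fps)
    n_s, n_e = count_approaches(labels, min_dwell)
    v_s, v_e = sector_velocity(traj, labels)
    return TrialMetrics(
        subject_id=traj.subject_id,
        t_stimulus=t_s,
        t_empty=t_e,
        n_approach_stimulus=n_s,
        n_approach_empty=n_e,
        v_stimulus=v_s,
        v_empty=v_e,
        activity_fraction=activity_fraction(traj, speed_floor),
        test_duration=traj.duration_s,
    )


def apply_exclusion(metrics: TrialMetrics, mode: str) -> TrialMetrics:
    """Apply the assay's 5% discard rule; flags, never deletes.

    ``two_circles`` (object test): excluded when the subject moved less than
    5% of the trial (reason ``immobility``).  ``three_thirds`` (odor test):
    excluded when combined time in the two end sections is below 5% of the
    trial (reason ``nonchooser``).
    """
    if mode == "two_circles":
        if metrics.activity_fraction < EXCLUSION_FRACTION:
            return replace(metrics, included=False, exclusion_reason="immobility")
    elif mode == "three_thirds":
        if metrics.t_stimulus + metrics.t_empty < EXCLUSION_FRACTION * metrics.test_duration:
            return replace(metrics, included=False, exclusion_reason="nonchooser")
    else:
        raise ValueError(f"unknown exclusion mode: {mode!r}")
    return replace(metrics, included=True, exclusion_reason=None)


def preference(metrics: TrialMetrics) -> PreferenceRecord:
    """Percentage preference for the stimulus, with the totals as weights.

    percent_time = t_stimulus / (t_stimulus + t_empty) x 100, and likewise
    for approaches; equal occupancy gives exactly the 50% chance level.
    """
    wt = metrics.t_stimulus + metrics.t_empty
    wa = metrics.n_approach_stimulus + metrics.n_approach_empty
    if wt <= 0:
        raise UndefinedPreferenceError(
            f"{metrics.subject_id}: no time in either choice sector"
        )
    if wa <= 0:
        raise UndefinedPreferenceError(
            f"{metrics.subject_id}: no approaches to either choice sector"
        )
    return PreferenceRecord(
        percent_time=100.0 * metrics.t_stimulus / wt,
        percent_approach=100.0 * metrics.n_approach_stimulus / wa,
        weight_time=wt,
        weight_approach=float(wa),
    )


def score_cohort(
    trajectories: list[Trajectory],
    arena: ArenaConfig,
    min_dwell: int = DEFAULT_MIN_DWELL,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
) -> pd.DataFrame:
    """Score every subject; one row per subject, excluded rows kept flagged.

    Preference columns are NaN for excluded or undefined subjects.
    """
    rows = []
    for traj in trajectories:
        m = apply_exclusion(compute_trial_metrics(traj, arena, min_dwell, speed_floor), arena.mode)
        row = m.__dict__.copy()
        row["exclusion_reason"] = m.exclusion_reason or ""
        # totals are defined even when a preference is not
        row["weight_time"] = m.t_stimulus + m.t_empty
        row["weight_approach"] = float(m.n_approach_stimulus + m.n_approach_empty)
        row["percent_time"] = np.nan
        row["percent_approach"] = np.nan
        if m.included:
            try:
                pref = preference(m)
                row["percent_time"] = pref.percent_time
                row["percent_approach"] = pref.percent_approach
            except UndefinedPreferenceError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
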