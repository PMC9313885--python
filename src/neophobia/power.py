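"""Cohort-level Monte-Carlo utilities: type-I-error and power studies.

These helpers run whole replicate cohorts through the simulate → score →
analyse chain without building per-subject :class:`Trajectory` objects or
rendering video, which keeps a 1000-replicate calibration tractable.  The
scoring here is the array form of the per-subject functions in
:mod:`neophobia.metrics`; the test suite checks the two routes agree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arena import EMPTY, STIMULUS, ArenaConfig
from .metrics import (
    DEFAULT_MIN_DWELL,
    DEFAULT_SPEED_FLOOR,
    EXCLUSION_FRACTION,
    _count_runs,
)
from .simulate import CohortDesign, SimParams, _simulate_paths
from .stats import arcsine_sqrt, weighted_ancova, weighted_t_test


def _design_vectors(design: CohortDesign) -> pd.DataFrame:
    rows = []
    k = 0
    for treatment, age in design.cells:
        for _ in range(design.n_per_cell):
            sf = (
                design.speed_factor_by_cell.get((treatment, age), 1.0)
                if design.speed_factor_by_cell
                else 1.0
            )
            rows.append(
                {
                    "subject_id": f"s{k:03d}",
                    "treatment": treatment,
                    "age_dpf": age,
                    "attraction": design.attraction_by_cell[(treatment, age)],
                    "speed_factor": sf,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def score_paths(
    x: np.ndarray,
    y: np.ndarray,
    arena: ArenaConfig,
    fps: float,
    min_dwell: int = DEFAULT_MIN_DWELL,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
) -> pd.DataFrame:
    """Score an (n_subjects, n_frames) batch of paths; one row per subject."""
    labels = arena.sector_labels(x, y)
    n, n_frames = x.shape
    t_stim = (labels == STIMULUS).sum(axis=1) / fps
    t_empty = (labels == EMPTY).sum(axis=1) / fps
    speeds = np.hypot(np.diff(x, axis=1), np.diff(y, axis=1)) * fps
    activity = (speeds > speed_floor).mean(axis=1)
    start = labels[:, :-1]

    def _sector_mean(code: int) -> np.ndarray:
        mask = start == code
        cnt = mask.sum(axis=1)
        tot = np.where(mask, speeds, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    v_stim = _sector_mean(STIMULUS)
    v_empty = _sector_mean(EMPTY)
    n_app_s = np.array([_count_runs(labels[i] == STIMULUS, min_dwell) for i in range(n)])
    n_app_e = np.array([_count_runs(labels[i] == EMPTY, min_dwell) for i in range(n)])
    duration = n_frames / fps
    df = pd.DataFrame(
        {
            "t_stimulus": t_stim,
            "t_empty": t_empty,
            "n_approach_stimulus": n_app_s,
            "n_approach_empty": n_app_e,
            "v_stimulus": v_stim,
            "v_empty": v_empty,
            "activity_fraction": activity,
            "test_duration": duration,
        }
    )
    if arena.mode == "two_circles":
        df["included"] = df["activity_fraction"] >= EXCLUSION_FRACTION
        df["exclusion_reason"] = np.where(df["included"], "", "immobility")
    else:
        chose = df["t_stimulus"] + df["t_empty"] >= EXCLUSION_FRACTION * duration
        df["included"] = chose
        df["exclusion_reason"] = np.where(chose, "", "nonchooser")
    wt = df["t_stimulus"] + df["t_empty"]
    wa = df["n_approach_stimulus"] + df["n_approach_empty"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["percent_time"] = np.where(wt > 0, 100.0 * df["t_stimulus"] / wt, np.nan)
        df["percent_approach"] = np.where(
            wa > 0, 100.0 * df["n_approach_stimulus"] / wa, np.nan
        )
    df["weight_time"] = wt
    df["weight_approach"] = wa.astype(float)
    return df


def simulate_cohort_tables(
    design: CohortDesign,
    params: SimParams,
    arena: ArenaConfig,
    n_replicates: int,
    seed: int,
    chunk: int = 40,
    min_dwell: int = DEFAULT_MIN_DWELL,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
):
    """Yield one scored cohort table (metrics + design columns) per replicate.

    Replicates are batched ``chunk`` cohorts at a time into one vectorised
    simulation pass; the stream is seeded once, so results depend only on
    ``seed`` and the replicate order.
    """
    base = _design_vectors(design)
    n_subj = len(base)
    rng = np.random.default_rng(seed)
    beta = base["attraction"].to_numpy()
    sfac = base["speed_factor"].to_numpy()
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        x, y = _simulate_paths(
            m * n_subj,
            params,
            arena,
            rng,
            attraction=np.tile(beta, m),
            speed_factor=np.tile(sfac, m),
        )
        for r in range(m):
            sl = slice(r * n_subj, (r + 1) * n_subj)
            tab = score_paths(x[sl], y[sl], arena, params.fps, min_dwell, speed_floor)
            yield pd.concat(
                [base[["subject_id", "treatment", "age_dpf"]].reset_index(drop=True), tab],
                axis=1,
            )
        done += m
        del x, y


def ancova_on_cohort(table: pd.DataFrame, response: str = "percent_time") -> "pd.DataFrame":
    """Weighted ANCOVA (arcsine-sqrt transformed) on one scored cohort table."""
    weights = "weight_time" if response == "percent_time" else "weight_approach"
    sub = table[table["included"] & table[response].notna() & (table[weights] > 0)].copy()
    sub["y"] = arcsine_sqrt(np.clip(sub[response] / 100.0, 0.0, 1.0))
    res = weighted_ancova(sub, "y", weights=weights)
    return res


def rejection_rates(
    design: CohortDesign,
    params: SimParams,
    arena: ArenaConfig,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    response: str = "percent_time",
    posthoc: bool = False,
) -> pd.DataFrame:
    """Per-term rejection rates of the weighted ANCOVA over replicates.

    With ``posthoc`` the per-age pairwise weighted t-tests on the treatment
    contrast are recorded too (columns ``posthoc_<age>``).
    """
    weights = "weight_time" if response == "percent_time" else "weight_approach"
    records = []
    for tab in simulate_cohort_tables(design, params, arena, n_replicates, seed):
        res = ancova_on_cohort(tab, response)
        rec = {t.term: t.p < alpha for t in res.tests}
        if posthoc:
            sub = tab[tab["included"] & tab[response].notna() & (tab[weights] > 0)].copy()
            sub["y"] = arcsine_sqrt(np.clip(sub[response] / 100.0, 0.0, 1.0))
            for age in sorted(sub["age_dpf"].unique()):
                cell = sub[sub["age_dpf"] == age]
                t = weighted_t_test(cell, "y", "treatment", weights=weights)
                rec[f"posthoc_{age}"] = t.tests[0].p < alpha
        records.append(rec)
    return pd.DataFrame(records)
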