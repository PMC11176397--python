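"""Behavioral, perfusion, survival and phagocytosis summaries, and the
EEG-behavior correlation analyses.

Covers: open-field trajectory metrics (ambulatory distance, percent time
in a central zone, counterclockwise:clockwise rotation ratio), regional
cerebral blood flow percent drop, group mortality percentages, Spearman
correlation of a quantitative-EEG metric against the Garcia neurological
score, the rat-to-human body-surface-area dose conversion, and
beads-per-cell phagocytosis summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "OpenFieldMetrics",
    "open_field_metrics",
    "rcbf_drop",
    "mortality_summary",
    "correlate_eeg_behavior",
    "hed_convert",
    "phagocytosis_summary",
]


@dataclass(frozen=True)
class OpenFieldMetrics:
    ambulatory_distance: float
    center_time_pct: float
    ccw_rotations: int
    cw_rotations: int
    ccw_cw_ratio: float  # NaN when no clockwise rotations


def open_field_metrics(xy: np.ndarray, arena_side: float,
                       center_fraction: float = 0.5) -> OpenFieldMetrics:
    """Trajectory metrics for one open-field trial.

    ``xy`` is an (n, 2) array of positions in arena coordinates
    [0, arena_side] x [0, arena_side].  The center zone is the concentric
    square with side ``center_fraction * arena_side``.  Rotations are
    counted by integrating the signed step-heading change: each completed
    +/-360 degrees increments the CCW/CW count.
    """
    p = np.asarray(xy, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
        raise ValueError("trajectory must be an (n>=2, 2) position array")
    if (p < 0).any() or (p > arena_side).any():
        raise ValueError("trajectory leaves the arena bounds")
    steps = np.diff(p, axis=0)
    distance = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    half = center_fraction * arena_side / 2.0
    c = arena_side / 2.0
    inside = (np.abs(p[:, 0] - c) <= half) & (np.abs(p[:, 1] - c) <= half)
    center_pct = 100.0 * float(inside.mean())
    moving = np.hypot(steps[:, 0], steps[:, 1]) > 0
    headings = np.arctan2(steps[moving, 1], steps[moving, 0])
    ccw = cw = 0
    if len(headings) >= 2:
        dtheta = np.diff(headings)
        dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
        acc = 0.0
        for d in dtheta:
            acc += d
            while acc >= 2 * np.pi:
                ccw += 1
                acc -= 2 * np.pi
            while acc <= -2 * np.pi:
                cw += 1
                acc += 2 * np.pi
    ratio = ccw / cw if cw > 0 else math.nan
    return OpenFieldMetrics(distance, center_pct, ccw, cw, ratio)


def rcbf_drop(baseline: float, values: Sequence[float]) -> np.ndarray:
    """Percent drop of regional cerebral blood flow from baseline at each
    post-occlusion time point; negative drops (hyperemia) are allowed."""
    if baseline <= 0:
        raise ValueError("baseline rCBF must be positive")
    v = np.asarray(values, dtype=float)
    return 100.0 * (baseline - v) / baseline


def mortality_summary(records: pd.DataFrame) -> dict[str, float]:
    """Percent mortality per group and overall, rounded to one decimal.

    ``records`` needs one row per animal with columns ``group`` and
    ``died`` (boolean event indicator; censored-alive animals False).
    """
    if not {"group", "died"}.issubset(records.columns):
        raise ValueError("records needs columns 'group' and 'died'")
    out: dict[str, float] = {}
    for group, sub in records.groupby("group", observed=True):
        if len(sub) == 0:
            continue
        out[str(group)] = round(100.0 * sub["died"].sum() / len(sub), 1)
    out["overall"] = round(100.0 * records["died"].sum() / len(records), 1)
    return out


def correlate_eeg_behavior(timecourse: pd.DataFrame, scores: pd.DataFrame,
                           metric: str = "spr",
                           score_col: str = "garcia") -> _stats.TestResult:
    """Spearman correlation between a qEEG metric and a behavior score
    over paired (subject, day) observations.

    ``timecourse`` is the tidy per-electrode frame from the qEEG stage
    (columns subject_id, day, electrode, metric, value); the metric is
    first averaged over electrodes within each (subject, day).  With fewer
    than 4 pairs the r value is still reported but the p-value is flagged
    unreliable.
    """
    tc = timecourse[timecourse["metric"] == metric]
    if tc.empty:
        raise ValueError(f"metric {metric!r} absent from timecourse")
    per_subj = (tc.groupby(["subject_id", "day"], observed=True)["value"]
                .mean().rename(metric).reset_index())
    merged = per_subj.merge(scores[["subject_id", "day", score_col]],
                            on=["subject_id", "day"], how="inner")
    if len(merged) < 2:
        raise ValueError("fewer than two paired observations")
    res = _stats.spearman(merged[metric], merged[score_col])
    if len(merged) < 4:
        res = _stats.TestResult(res.statistic, res.p_value, res.method,
                                df=res.df, n=res.n,
                                note="p unreliable: fewer than 4 pairs")
    return res


def hed_convert(animal_dose_mg_kg: float, species_factor: float = 6.2) -> float:
    """Human equivalent dose by body-surface-area scaling (rat factor
    6.2), rounded to two decimals."""
    if animal_dose_mg_kg < 0:
        raise ValueError("dose must be nonnegative")
    if species_factor <= 0:
        raise ValueError("species factor must be positive")
    return round(animal_dose_mg_kg / species_factor, 2)


def phagocytosis_summary(counts_by_condition: Mapping[str, Sequence[float]],
                         stimulus: str = "hemin",
                         reference: str = "vehicle") -> dict:
    """Per-condition beads-per-cell mean +/- SD, stimulus/reference fold
    change, and a two-sided Mann-Whitney p-value."""
    conds = dict(counts_by_condition)
    if stimulus not in conds or reference not in conds:
        keys = list(conds)
        if len(keys) != 2:
            raise ValueError("need the stimulus and reference conditions")
        stimulus, reference = keys
    out: dict = {"conditions": {}}
    for name, counts in conds.items():
        c = np.asarray(counts, dtype=float)
        if len(c) < 2:
            raise ValueError(f"condition {name!r} needs >= 2 cells")
        out["conditions"][name] = {
            "mean": float(c.mean()),
            "sd": float(c.std(ddof=1)),
            "n": int(len(c)),
        }
    ref_mean = out["conditions"][reference]["mean"]
    stim_mean = out["conditions"][stimulus]["mean"]
    out["fold_change"] = stim_mean / ref_mean if ref_mean > 0 else math.nan
    mw = _stats.mann_whitney(conds[stimulus], conds[reference])
    out["p_value"] = mw.p_value
    out["test"] = mw.method
    return out
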