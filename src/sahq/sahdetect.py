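"""MRI-based in vivo SAH classification.

The T2 hypointense volume at the skull base (V_hypo, mm^3) discriminates
hemorrhage from sham animals.  This module builds the empirical ROC curve
for that volume, computes its AUC two independent ways (trapezoid and
pairwise-comparison), selects the operating cutoff with 100% specificity,
and simulates the operating characteristics of a fixed published cutoff on
synthetic cohorts drawn from group summary statistics.

Classification convention throughout: positive (called SAH) iff
value > threshold; candidate thresholds sit at midpoints between adjacent
sorted unique values, with -inf/+inf endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROCResult",
    "roc_curve",
    "auc",
    "cutoff_at_full_specificity",
    "simulate_operating_point",
]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float | None = None
    cutoff_full_spec: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None


def _split(values, truth):
    v = np.asarray(values, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("values and truth must be equal-length 1-D")
    pos, neg = v[t], v[~t]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_curve(values, truth) -> ROCResult:
    """Empirical ROC over midpoint thresholds.

    ``truth`` is boolean (True = diseased/SAH).  Sensitivity is
    non-increasing and specificity non-decreasing in the threshold.
    """
    pos, neg = _split(values, truth)
    uniq = np.unique(np.concatenate([pos, neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos > th).mean() for th in thresholds])
    spec = np.array([(neg <= th).mean() for th in thresholds])
    return ROCResult(thresholds, sens, spec)


def auc(values, truth) -> float:
    """Pairwise-comparison AUC: fraction of (positive, negative) pairs with
    positive > negative, ties counting one half.  Identical to the
    trapezoidal area under the midpoint-threshold ROC curve.

    Computed via midranks (the rank-sum identity), so large cohorts avoid
    the quadratic pairwise matrix.
    """
    pos, neg = _split(values, truth)
    from .stats import _rank_average

    n1, n0 = len(pos), len(neg)
    ranks = _rank_average(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def trapezoid_auc(roc: ROCResult) -> float:
    """Trapezoidal area under the (1-specificity, sensitivity) curve.

    Thresholds ascend, so reversing gives a monotone path from (0,0) to
    (1,1); tied values produce diagonal segments whose trapezoids carry
    the half-tie credit.
    """
    x = (1.0 - roc.specificity)[::-1]
    y = roc.sensitivity[::-1]
    return float(np.trapezoid(y, x))


def cutoff_at_full_specificity(roc: ROCResult) -> tuple[float, float]:
    """Among thresholds with specificity exactly 1, return the one with
    maximal sensitivity (smallest threshold on ties)."""
    mask = roc.specificity >= 1.0
    sens = np.where(mask, roc.sensitivity, -1.0)
    best = sens.max()
    idx = int(np.nonzero(sens == best)[0][0])  # thresholds ascending
    return float(roc.thresholds[idx]), float(roc.sensitivity[idx])


def analyze_volumes(values, truth) -> ROCResult:
    """Full ROC analysis: curve, AUC, and the 100%-specificity cutoff."""
    roc = roc_curve(values, truth)
    a = auc(values, truth)
    cut, sens = cutoff_at_full_specificity(roc)
    return ROCResult(roc.thresholds, roc.sensitivity, roc.specificity,
                     auc=a, cutoff_full_spec=cut, sens_at_cutoff=sens,
                     spec_at_cutoff=1.0)


def simulate_operating_point(vparams, cutoff: float, n_sah: int, n_sham: int,
                             n_reps: int, seed: int) -> tuple[float, float]:
    """Median per-cohort sensitivity and specificity of a fixed cutoff.

    Each replicate draws a cohort via the synthetic V_hypo generator
    (zero-truncated Gaussians per group) and classifies at ``cutoff`` with
    the strictly-greater rule.  Returns (median sensitivity, median
    specificity) as fractions in [0, 1].
    """
    from .synthetic_cohort import gen_vhypo

    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable median")
    if n_sah < 1 or n_sham < 1:
        raise ValueError("need at least one animal per group")
    rng_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    sens = np.empty(n_reps)
    spec = np.empty(n_reps)
    for i, ss in enumerate(rng_seeds):
        rep_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        tbl = gen_vhypo(vparams, n_sah=n_sah, n_sham=n_sham, seed=rep_seed)
        v = tbl["v_hypo_mm3"].to_numpy()
        is_sah = (tbl["group"] == "SAH").to_numpy()
        sens[i] = (v[is_sah] > cutoff).mean()
        spec[i] = (v[~is_sah] <= cutoff).mean()
    return float(np.median(sens)), float(np.median(spec))
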