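"""Statistical tests used throughout the analysis pipeline.

All test statistics are computed from first principles (rank assignment,
exact U-distribution counting, balanced sums-of-squares decomposition,
product-limit survival estimation, log-rank O/E/V accumulation).  SciPy is
used only for reference distribution functions (t, F, normal, chi-square)
when converting a statistic into a p-value.

Every public function returns a :class:`TestResult` so callers can treat
the toolbox uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _dist

__all__ = [
    "TestResult",
    "SurvivalCurve",
    "spearman",
    "mann_whitney",
    "t_test_independent",
    "sidak_adjust",
    "factorial_anova",
    "kaplan_meier",
    "log_rank",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: object = None
    n: object = None
    note: str | None = None


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) step function.

    ``survival[i]`` is S(t) for t in [times[i], times[i+1]); S(0) = 1 is
    implicit (``times`` holds distinct event times only).
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
        return s


def _rank_average(x: np.ndarray) -> np.ndarray:
    """Midranks: average rank for ties, 1-based."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(xc @ yc) / denom


def spearman(x: Sequence[float], y: Sequence[float], method: str = "auto") -> TestResult:
    """Spearman rank correlation with midrank tie handling.

    The p-value uses the t approximation t = r*sqrt((n-2)/(1-r^2)) with
    n-2 df.  ``method='exact'`` (available for n <= 8) enumerates all
    pairings of the observed ranks instead; ``'auto'`` keeps the
    t approximation at every n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    rx, ry = _rank_average(x), _rank_average(y)
    r = _pearson(rx, ry)
    if math.isnan(r):
        return TestResult(math.nan, math.nan, "spearman", n=n,
                          note="undefined: constant input vector")
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        robs = abs(r)
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= robs - 1e-12:
                count += 1
        return TestResult(r, count / total, "spearman (exact permutation)", n=n)
    if abs(r) >= 1.0:
        p = 0.0
    elif n < 3:
        p = 1.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * _dist.t.sf(abs(t), n - 2)
    return TestResult(r, min(p, 1.0), "spearman", df=n - 2, n=n)


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Number of rank arrangements with each U value (no ties).

    Recurrence c(n1,n2; u) = c(n1-1,n2; u-n2) + c(n1,n2-1; u).
    """
    if n1 == 0 or n2 == 0:
        return (1.0,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = [0.0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 alternative: str = "two-sided",
                 method: str = "auto") -> TestResult:
    """Mann-Whitney U test; U counts pairs where ``a`` exceeds ``b``.

    Exact p (enumeration of the tie-free U distribution) is used when both
    samples are small and untied; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = _rank_average(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    use_exact = method == "exact" or (
        method == "auto" and not has_ties and n1 * n2 <= 400
    )
    if use_exact and not has_ties:
        counts = np.asarray(_u_counts(n1, n2))
        total = counts.sum()
        ui = int(round(u))
        lower = counts[: ui + 1].sum() / total
        upper = counts[ui:].sum() / total
        if alternative == "less":
            p = lower
        elif alternative == "greater":
            p = upper
        else:
            p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(u, float(p), "mann-whitney (exact)", n=(n1, n2))
    # tie-corrected normal approximation with continuity correction
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((t_counts ** 3) - t_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(u, 1.0, "mann-whitney (normal approx)", n=(n1, n2),
                          note="degenerate: all values tied")
    if alternative == "less":
        z = (u - mu + 0.5) / math.sqrt(var)
        p = _dist.norm.cdf(z)
    elif alternative == "greater":
        z = (u - mu - 0.5) / math.sqrt(var)
        p = _dist.norm.sf(z)
    else:
        z = (abs(u - mu) - 0.5) / math.sqrt(var)
        p = 2.0 * _dist.norm.sf(max(z, 0.0))
    return TestResult(u, float(min(p, 1.0)), "mann-whitney (normal approx)",
                      n=(n1, n2))


def t_test_independent(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pooled-variance two-sided independent-samples t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two observations")
    df = n1 + n2 - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, "t-test (pooled)", df=df, n=(n1, n2))
        return TestResult(math.inf if diff > 0 else -math.inf, 0.0,
                          "t-test (pooled)", df=df, n=(n1, n2),
                          note="degenerate: zero pooled variance, unequal means")
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * _dist.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), "t-test (pooled)",
                      df=df, n=(n1, n2))


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment: 1 - (1-p)^m, capped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"number of comparisons m must be >= 1, got {m}")
    if p == 1.0:
        return 1.0
    # -expm1(m*log1p(-p)) keeps precision for tiny p
    return min(1.0, -math.expm1(m * math.log1p(-p)))


def factorial_anova(values: Sequence[float],
                    factors: Mapping[str, Sequence],
                    block: Sequence | None = None) -> dict[str, TestResult]:
    """Balanced fixed-effects factorial ANOVA (1-3 factors).

    Decomposes the total sum of squares into all main effects and
    interactions by successive cell-mean differencing; requires a complete,
    balanced design (equal counts in every cell of the full cross).  An
    optional ``block`` factor (e.g. subject, for repeated-measures layouts)
    is removed additively before the residual is formed.

    Returns a mapping from effect name (``"group"``, ``"group:day"``, ...)
    to :class:`TestResult`; a ``"residual"`` entry carries the residual df
    in its ``df`` field.
    """
    y = np.asarray(values, dtype=float)
    names = list(factors)
    if not 1 <= len(names) <= 3:
        raise ValueError("factorial_anova supports 1 to 3 factors")
    df_data = pd.DataFrame({name: list(lv) for name, lv in factors.items()})
    if len(df_data) != len(y):
        raise ValueError("factor label lengths must match values")
    df_data["_y"] = y
    levels = {name: df_data[name].nunique() for name in names}
    cells = df_data.groupby(names, observed=True).size()
    n_cells_expected = int(np.prod([levels[f] for f in names]))
    if len(cells) != n_cells_expected or cells.nunique() != 1:
        raise ValueError(
            "unbalanced or incomplete design; fit an unbalanced/mixed model "
            "with statsmodels or lme4 instead"
        )
    n = len(y)
    grand = y.mean()
    total_ss = float(((y - grand) ** 2).sum())
    effect_arrays: dict[tuple, np.ndarray] = {}
    results: dict[str, TestResult] = {}
    effect_ss: dict[tuple, float] = {}
    effect_df: dict[tuple, int] = {}
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            m = df_data.groupby(list(subset), observed=True)["_y"].transform("mean").to_numpy()
            e = m - grand
            for smaller_size in range(1, size):
                for sub2 in combinations(subset, smaller_size):
                    e = e - effect_arrays[sub2]
            effect_arrays[subset] = e
            effect_ss[subset] = float((e ** 2).sum())
            effect_df[subset] = int(np.prod([levels[f] - 1 for f in subset]))
    ss_model = sum(effect_ss.values())
    df_model = sum(effect_df.values())
    ss_block = 0.0
    df_block = 0
    if block is not None:
        blk = pd.Series(list(block))
        if len(blk) != n:
            raise ValueError("block labels must match values length")
        bm = blk.map(df_data.groupby(blk)["_y"].mean()).to_numpy()
        ss_block = float(((bm - grand) ** 2).sum())
        df_block = blk.nunique() - 1
    ss_res = max(total_ss - ss_model - ss_block, 0.0)
    df_res = n - 1 - df_model - df_block
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ms_res = ss_res / df_res
    for subset in effect_ss:
        name = ":".join(subset)
        ss, d = effect_ss[subset], effect_df[subset]
        if ss <= 1e-12 * max(total_ss, 1.0):
            results[name] = TestResult(0.0, 1.0, "anova F", df=(d, df_res), n=n)
            continue
        if ms_res == 0.0:
            results[name] = TestResult(math.inf, 0.0, "anova F", df=(d, df_res),
                                       n=n, note="zero residual variance")
            continue
        f = (ss / d) / ms_res
        p = float(_dist.f.sf(f, d, df_res))
        results[name] = TestResult(float(f), p, "anova F", df=(d, df_res), n=n)
    results["residual"] = TestResult(ss_res, math.nan, "residual SS",
                                     df=(df_res,), n=n)
    return results


def _as_duration_event(durations, events):
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if d.shape != e.shape or d.ndim != 1:
        raise ValueError("durations and events must be equal-length 1-D")
    if (d < 0).any():
        raise ValueError("durations must be nonnegative")
    return d, e


def kaplan_meier(durations: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate; S(0)=1, non-increasing by construction."""
    d, e = _as_duration_event(durations, events)
    event_times = np.unique(d[e])
    times, at_risk, n_events, surv = [], [], [], []
    s = 1.0
    for t in event_times:
        nr = int((d >= t).sum())
        de = int(((d == t) & e).sum())
        s *= 1.0 - de / nr
        times.append(t)
        at_risk.append(nr)
        n_events.append(de)
        surv.append(s)
    return SurvivalCurve(np.asarray(times), np.asarray(at_risk),
                         np.asarray(n_events), np.asarray(surv))


def log_rank(durations1, events1, durations2, events2) -> TestResult:
    """Two-group log-rank (Mantel-Cox) test with the discrete
    hypergeometric variance at tied event days; 1 df chi-square."""
    d1, e1 = _as_duration_event(durations1, events1)
    d2, e2 = _as_duration_event(durations2, events2)
    all_times = np.unique(np.concatenate([d1[e1], d2[e2]]))
    o1 = exp1 = var = 0.0
    for t in all_times:
        n1 = int((d1 >= t).sum())
        n2 = int((d2 >= t).sum())
        nt = n1 + n2
        dt = int(((d1 == t) & e1).sum()) + int(((d2 == t) & e2).sum())
        if nt == 0 or dt == 0:
            continue
        o1 += int(((d1 == t) & e1).sum())
        exp1 += dt * n1 / nt
        if nt > 1:
            var += dt * (n1 / nt) * (1 - n1 / nt) * (nt - dt) / (nt - 1)
    if var == 0.0:
        return TestResult(0.0, 1.0, "log-rank", df=1,
                          n=(len(d1), len(d2)), note="no informative events")
    chi2 = (o1 - exp1) ** 2 / var
    p = float(_dist.chi2.sf(chi2, 1))
    return TestResult(float(chi2), p, "log-rank", df=1, n=(len(d1), len(d2)))
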