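"""Comparison suite: spatial point pattern test, rank test, effect sizes.

Simulated roost patterns are compared with an observed pattern by an
area-based nonparametric spatial point pattern test over the hexagonal
tessellation, reporting the robust global S-index (the share of similar
cells among cells that contain points from either pattern).  Univariate
outputs (group size, roost height, switching distance) are compared by the
Mann-Whitney U test and by Hedges' g, the bias-corrected standardized mean
difference, with magnitudes labelled by Cohen's thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .engine import SimulationResult, switching_distances
from .environment import HexGrid

__all__ = [
    "PointPattern",
    "SPPTResult",
    "EffectSizeResult",
    "SummaryStats",
    "sppt",
    "mann_whitney_u",
    "hedges_g",
    "summarize_result",
]


@dataclass
class PointPattern:
    """A labelled planar point set (metres)."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SPPTResult:
    per_cell: pd.DataFrame  # cell, base_pct, ci_lo, ci_hi, similar, significant
    s_global: float
    s_robust: float
    n_cells_used: int


@dataclass
class EffectSizeResult:
    mean_diff: float
    ci_mean_diff: tuple[float, float]
    g: float
    ci_g: tuple[float, float]
    magnitude: str


def _cell_percentages(points: np.ndarray, grid: HexGrid) -> np.ndarray:
    cells = grid.assign(points[:, 0], points[:, 1])
    if np.any(cells < 0):
        raise ValueError("point pattern extends outside the tessellation")
    counts = np.bincount(cells, minlength=grid.n_cells).astype(float)
    return 100.0 * counts / counts.sum()


def sppt(
    base: PointPattern,
    test: PointPattern,
    grid: HexGrid,
    n_boot: int = 200,
    sample_frac: float = 0.85,
    conf: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> SPPTResult:
    """Area-based spatial point pattern test with global and robust S-indices.

    For every cell, the base pattern's point percentage is compared with a
    nonparametric confidence interval built from ``n_boot`` subsamples of
    ``sample_frac`` of the test pattern (drawn without replacement).  A cell
    is similar when the base percentage falls inside the interval.  S_global
    divides similar cells by all cells; the robust S divides similar cells
    that contain points of either pattern by all such non-empty cells.
    """
    if len(base) == 0 or len(test) == 0:
        raise ValueError("both point patterns must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    base_cells = grid.assign(base.points[:, 0], base.points[:, 1])
    test_cells = grid.assign(test.points[:, 0], test.points[:, 1])
    if np.any(base_cells < 0) or np.any(test_cells < 0):
        raise ValueError("point pattern extends outside the tessellation")
    base_pct = 100.0 * np.bincount(base_cells, minlength=grid.n_cells) / len(base)

    m = max(1, int(math.floor(sample_frac * len(test))))
    boot = np.empty((n_boot, grid.n_cells))
    for bidx in range(n_boot):
        take = rng.choice(len(test), size=m, replace=False)
        boot[bidx] = 100.0 * np.bincount(
            test_cells[take], minlength=grid.n_cells
        ) / m
    alpha = 1.0 - conf
    lo = np.percentile(boot, 100 * alpha / 2.0, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha / 2.0), axis=0)
    similar = (base_pct >= lo) & (base_pct <= hi)

    nonempty = (
        np.bincount(base_cells, minlength=grid.n_cells)
        + np.bincount(test_cells, minlength=grid.n_cells)
    ) > 0
    n_used = int(nonempty.sum())
    per_cell = pd.DataFrame(
        {
            "cell": np.arange(grid.n_cells),
            "base_pct": base_pct,
            "ci_lo": lo,
            "ci_hi": hi,
            "similar": similar,
            "significant": ~similar,
            "nonempty": nonempty,
        }
    )
    s_global = float(similar.mean())
    s_robust = float(similar[nonempty].mean()) if n_used else float("nan")
    return SPPTResult(per_cell, s_global, s_robust, n_used)


def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """PMF of U under the null (no ties), by the counting recurrence.

    c[i, j, u] counts rank arrangements of i x's and j y's with U = u;
    conditioning on whether the largest value is an x (it then beats all j
    y's) gives c[i, j, u] = c[i-1, j, u-j] + c[i, j-1, u].
    """
    max_u = n1 * n2
    c = np.zeros((n1 + 1, n2 + 1, max_u + 1))
    c[:, :, 0] = 0.0
    c[0, :, 0] = 1.0
    c[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            c[i, j, j:] += c[i - 1, j, : max_u + 1 - j]
            c[i, j, :] += c[i, j - 1, :]
    pmf = c[n1, n2]
    return pmf / pmf.sum()


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (statistic of the first sample) with two-sided p.

    U is computed from midranks.  Without ties and for n1*n2 <= 400 the
    p-value is exact (dynamic-programming null distribution); otherwise the
    tie-corrected normal approximation with continuity correction is used.
    Degenerate input (all values identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if len(tie_counts) == 1:
        return float(u1), 1.0  # degenerate: all values identical
    if not has_ties and n1 * n2 <= 400:
        pmf = _exact_u_pmf(n1, n2)
        mu = n1 * n2 / 2.0
        dev = abs(u1 - mu)
        us = np.arange(len(pmf))
        p = float(pmf[np.abs(us - mu) >= dev - 1e-9].sum())
        return float(u1), min(1.0, p)
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * norm.sf(max(z, 0.0))
    return float(u1), float(min(1.0, p))


_COHEN_THRESHOLDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def cohen_magnitude(g: float) -> str:
    """Cohen's qualitative label for a standardized mean difference."""
    for threshold, label in _COHEN_THRESHOLDS:
        if abs(g) < threshold:
            return label
    return "large"


def hedges_g(
    x,
    y,
    conf: float = 0.95,
    n_boot: int = 10000,
    rng: np.random.Generator | int | None = 0,
) -> EffectSizeResult:
    """Hedges' g with small-sample correction, CIs and Cohen magnitude.

    g = J * (mean(x) - mean(y)) / s_pooled with J = 1 - 3/(4*df - 1),
    df = n1 + n2 - 2.  The CI of g uses the asymptotic variance of the
    standardized mean difference; the CI of the raw mean difference is a
    seeded percentile bootstrap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per sample")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    )
    if s_pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    diff = float(x.mean() - y.mean())
    g = correction * diff / s_pooled
    var_g = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * df)
    zcrit = norm.ppf(0.5 + conf / 2.0)
    ci_g = (g - zcrit * math.sqrt(var_g), g + zcrit * math.sqrt(var_g))

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = rng.choice(x, n1).mean() - rng.choice(y, n2).mean()
    alpha = 1.0 - conf
    ci_diff = (
        float(np.percentile(boots, 100 * alpha / 2)),
        float(np.percentile(boots, 100 * (1 - alpha / 2))),
    )
    return EffectSizeResult(
        mean_diff=diff,
        ci_mean_diff=ci_diff,
        g=float(g),
        ci_g=(float(ci_g[0]), float(ci_g[1])),
        magnitude=cohen_magnitude(g),
    )


@dataclass
class SummaryStats:
    """Season-level medians and ranges of the daily roost records."""

    groups_per_day: tuple[float, float, float]  # median, min, max
    group_size: tuple[float, float, float]
    max_group_size_mean: float
    max_group_size: tuple[float, float, float]
    roost_height: tuple[float, float, float]
    max_group_roost_height: tuple[float, float, float]
    switching_distance: tuple[float, float, float] | None

    def to_dict(self) -> dict:
        return {
            "groups_per_day": self.groups_per_day,
            "group_size": self.group_size,
            "max_group_size_mean": self.max_group_size_mean,
            "max_group_size": self.max_group_size,
            "roost_height": self.roost_height,
            "max_group_roost_height": self.max_group_roost_height,
            "switching_distance": self.switching_distance,
        }


def _mmr(values) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def summarize_result(result: SimulationResult | pd.DataFrame) -> SummaryStats:
    """Medians and min-max ranges of the per-day simulation outputs."""
    records = result.records if isinstance(result, SimulationResult) else result
    if len(records) == 0:
        raise ValueError("no records to summarize")
    per_day = records.groupby("day")["cavity_id"].count()
    maxg = records[records["is_maximum_group"]]
    dist = switching_distances(records)
    return SummaryStats(
        groups_per_day=_mmr(per_day),
        group_size=_mmr(records["group_size"]),
        max_group_size_mean=float(maxg["group_size"].mean()),
        max_group_size=_mmr(maxg["group_size"]),
        roost_height=_mmr(records["roost_height"]),
        max_group_roost_height=_mmr(maxg["roost_height"]),
        switching_distance=_mmr(dist) if len(dist) else None,
    )
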