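"""Cavity field, hexagonal tessellation, roost quality and excrement dynamics.

The simulated roosting habitat is a ~128 ha woodland patch holding 944 tree
cavities, centred in a 9000 x 9000 m plane that bounds nightly flight.  The
patch is tessellated into 37 equal hexagonal cells; cavity density and mean
entrance height vary between cells (8-92 cavities per cell, mean heights
4.8-13.5 m).  A cavity's attractiveness for roosting (QR) combines its
relative entrance height with its load of excrements (LE, a 0-100 proxy for
the parasite load of accumulated guano).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "Cavity",
    "CavityField",
    "HexGrid",
    "QualityWeights",
    "build_hex_grid",
    "generate_synthetic_environment",
    "load_cavities",
    "save_cavities",
    "roost_quality",
    "roost_quality_field",
    "update_excrement_load",
    "assign_hex_cells",
]

#: total habitat area in m^2 (128.2 ha) shared equally by the 37 grid cells
HABITAT_AREA_M2 = 1.282e6
N_CELLS = 37
PLANE_SIZE = 9000.0
CELL_COUNT_RANGE = (8, 92)
CELL_MEAN_HEIGHT_RANGE = (4.8, 13.5)
MAX_CAVITY_HEIGHT = 16.0  # truncation ceiling for generated heights, m
LE_PER_SECOND_PER_BAT = 5e-5
LE_DAILY_DECREASE = 10.0
LE_DAILY_INCREASE_PER_BAT = 0.1
ATTRACTION_RADIUS_RANGE = (80.0, 100.0)


@dataclass
class Cavity:
    """One tree hollow: position, entrance height (CH) and occupancy state."""

    id: int
    x: float
    y: float
    height: float
    excrement_load: float = 0.0
    n_roosting: int = 0
    n_signalling: int = 0
    attraction_radius: float = 90.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError(f"cavity {self.id}: height must be > 0, got {self.height}")
        if not 0.0 <= self.excrement_load <= 100.0:
            raise ValueError(f"cavity {self.id}: excrement load outside [0, 100]")


@dataclass
class QualityWeights:
    """Weights of cavity height and excrement load in the QR score."""

    w_ch: float = 0.5
    w_le: float = 0.5

    def __post_init__(self) -> None:
        if self.w_ch < 0 or self.w_le < 0:
            raise ValueError("quality weights must be non-negative")


class HexGrid:
    """37 equal pointy-top hexagons tessellating the roosting area.

    Cells are a contiguous, symmetric subset of a hexagonal lattice (rows of
    3/4/5/4/5/4/5/4/3 cells) centred in the plane, sized so the 37 cells
    jointly cover the full habitat area.
    """

    def __init__(self, centers: np.ndarray, radius: float) -> None:
        self.centers = np.asarray(centers, dtype=float)
        self.radius = float(radius)
        self.polygons = [self._hexagon(cx, cy, self.radius) for cx, cy in self.centers]

    @staticmethod
    def _hexagon(cx: float, cy: float, r: float) -> Polygon:
        ang = np.deg2rad(np.arange(30, 390, 60))
        return Polygon(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))

    @property
    def n_cells(self) -> int:
        return len(self.polygons)

    @property
    def cell_area(self) -> float:
        return 1.5 * math.sqrt(3.0) * self.radius**2

    def bounds(self) -> tuple[float, float, float, float]:
        xs = [p.bounds for p in self.polygons]
        arr = np.array(xs)
        return (arr[:, 0].min(), arr[:, 1].min(), arr[:, 2].max(), arr[:, 3].max())

    def assign(self, x: np.ndarray, y: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Cell index for each point; -1 if a point lies outside every cell.

        In a hexagonal tessellation the cells are the Voronoi regions of
        their centres, so nearest-centre assignment is exact; containment in
        the nearest cell (with tolerance) rejects points outside the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d2 = (x[:, None] - self.centers[None, :, 0]) ** 2 + (
            y[:, None] - self.centers[None, :, 1]
        ) ** 2
        nearest = np.argmin(d2, axis=1)
        out = nearest.copy()
        pts = shapely.points(x, y)
        for i, (pt, cell) in enumerate(zip(pts, nearest)):
            if self.polygons[cell].distance(pt) > tol:
                out[i] = -1
        return out


def build_hex_grid(
    center: tuple[float, float] = (PLANE_SIZE / 2, PLANE_SIZE / 2),
    total_area_m2: float = HABITAT_AREA_M2,
) -> HexGrid:
    """Build the default 37-cell grid centred in the flight plane."""
    radius = math.sqrt(total_area_m2 / N_CELLS / (1.5 * math.sqrt(3.0)))
    dx = math.sqrt(3.0) * radius
    dy = 1.5 * radius
    cx, cy = center
    centers: list[tuple[float, float]] = []
    row_slots = [3, 4, 5, 4, 5, 4, 5, 4, 3]
    for row, n_slots in enumerate(row_slots):
        y = cy + (row - 4) * dy
        # odd slot counts centre on integer lattice columns, even counts on
        # half-offsets, so alternating 3/4/5 rows stagger automatically
        xs = cx + (np.arange(n_slots) - (n_slots - 1) / 2.0) * dx
        centers.extend((float(x), float(y)) for x in xs)
    assert len(centers) == N_CELLS
    return HexGrid(np.array(centers), radius)


class CavityField:
    """Column-oriented cavity table plus the mutable occupancy state.

    Attributes are flat numpy arrays indexed by cavity position (ids are
    0..n-1 for generated fields, arbitrary for loaded ones).
    """

    def __init__(
        self,
        ids: np.ndarray,
        xy: np.ndarray,
        height: np.ndarray,
        excrement: np.ndarray | None = None,
        plane_size: float = PLANE_SIZE,
    ) -> None:
        self.ids = np.asarray(ids, dtype=np.int64)
        self.xy = np.asarray(xy, dtype=float)
        self.height = np.asarray(height, dtype=float)
        if np.any(self.height <= 0):
            bad = int(self.ids[np.argmax(self.height <= 0)])
            raise ValueError(f"cavity {bad}: height must be > 0")
        n = len(self.ids)
        self.excrement = (
            np.zeros(n) if excrement is None else np.asarray(excrement, dtype=float)
        )
        self.n_roosting = np.zeros(n, dtype=np.int64)
        self.n_signalling = np.zeros(n, dtype=np.int64)
        self.attraction_radius = np.full(n, 90.0)
        self.plane_size = float(plane_size)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def max_height(self) -> float:
        return float(self.height.max())

    def cavity(self, index: int) -> Cavity:
        """Scalar view of one cavity (by array position, not id)."""
        return Cavity(
            id=int(self.ids[index]),
            x=float(self.xy[index, 0]),
            y=float(self.xy[index, 1]),
            height=float(self.height[index]),
            excrement_load=float(self.excrement[index]),
            n_roosting=int(self.n_roosting[index]),
            n_signalling=int(self.n_signalling[index]),
            attraction_radius=float(self.attraction_radius[index]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "z": self.height,
            }
        )

    def reset_occupancy(self) -> None:
        self.n_roosting[:] = 0
        self.n_signalling[:] = 0


def roost_quality(
    cavity: Cavity,
    max_height: float,
    weights: QualityWeights | None = None,
    t: float | None = None,
) -> float:
    """Roost quality QR of one cavity.

    QR = (100 * CH / max(CH)) * w_CH + (-(LE - 100)) * w_LE

    Relative entrance height rewards tall cavities; the excrement term decays
    linearly from 100 (pristine) to 0 (fully soiled).  With the default equal
    weights QR spans [0, 100].  ``t`` is accepted for signature symmetry with
    the time-varying LE but does not enter the formula.
    """
    if max_height <= 0:
        raise ValueError("max_height must be > 0")
    w = weights or QualityWeights()
    return (100.0 * cavity.height / max_height) * w.w_ch + (
        -1.0 * (cavity.excrement_load - 100.0)
    ) * w.w_le


def roost_quality_field(
    field: CavityField, weights: QualityWeights | None = None
) -> np.ndarray:
    """Vectorised QR for every cavity in the field."""
    w = weights or QualityWeights()
    return (100.0 * field.height / field.max_height) * w.w_ch + (
        -(field.excrement - 100.0)
    ) * w.w_le


def update_excrement_load(
    cavity: Cavity,
    n_bats: int,
    phase: str,
    seconds: float = 1.0,
) -> float:
    """Advance one cavity's excrement load LE and return the new value.

    ``phase='per-second-daytime'``: LE grows by 5e-5 per roosting bat per
    second of daytime roosting (``seconds`` seconds at once).
    ``phase='per-day'``: the end-of-day adjustment — an empty cavity loses 10
    (floored at 0), an occupied one gains 0.1 per bat (capped at 100).
    """
    if n_bats < 0:
        raise ValueError("n_bats must be >= 0")
    le = cavity.excrement_load
    if phase == "per-second-daytime":
        le += LE_PER_SECOND_PER_BAT * n_bats * seconds
    elif phase == "per-day":
        if n_bats == 0:
            le -= LE_DAILY_DECREASE
        else:
            le += LE_DAILY_INCREASE_PER_BAT * n_bats
    else:
        raise ValueError(f"unknown phase {phase!r}")
    le = min(100.0, max(0.0, le))
    cavity.excrement_load = le
    return le


def daytime_excrement_update(
    field: CavityField, n_bats: np.ndarray, daytime_seconds: float
) -> None:
    """Bulk LE update for one 16-h daytime block plus the daily adjustment.

    Applied once per simulated day: the per-second accumulation integrated
    over the roosting block, then the empty-cavity decrease / occupied-cavity
    increase.
    """
    n_bats = np.asarray(n_bats)
    if np.any(n_bats < 0):
        raise ValueError("n_bats must be >= 0")
    le = field.excrement
    le += LE_PER_SECOND_PER_BAT * n_bats * daytime_seconds
    occupied = n_bats > 0
    le[occupied] += LE_DAILY_INCREASE_PER_BAT * n_bats[occupied]
    le[~occupied] -= LE_DAILY_DECREASE
    np.clip(le, 0.0, 100.0, out=le)


def assign_hex_cells(
    field: CavityField, grid: HexGrid
) -> tuple[np.ndarray, pd.DataFrame]:
    """Map every cavity to its hex cell and summarise per-cell count and mean height.

    Raises if any cavity falls outside the tessellation, naming the cavity.
    """
    cells = grid.assign(field.xy[:, 0], field.xy[:, 1])
    if np.any(cells < 0):
        bad = int(field.ids[np.argmax(cells < 0)])
        raise ValueError(f"cavity {bad} lies outside every grid cell")
    counts = np.bincount(cells, minlength=grid.n_cells)
    mean_h = np.full(grid.n_cells, np.nan)
    for c in range(grid.n_cells):
        sel = cells == c
        if sel.any():
            mean_h[c] = field.height[sel].mean()
    summary = pd.DataFrame(
        {"cell": np.arange(grid.n_cells), "n_cavities": counts, "mean_height": mean_h}
    )
    return cells, summary


def _allocate_counts(
    n_cavities: int, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Skewed multinomial allocation repaired into the per-cell range."""
    lo, hi = CELL_COUNT_RANGE
    if not n_cells * lo <= n_cavities <= n_cells * hi:
        raise ValueError(
            f"n_cavities={n_cavities} infeasible for {n_cells} cells with "
            f"per-cell counts in [{lo}, {hi}]"
        )
    # exponential cell weights reproduce the published habitat's strong
    # density contrast (per-cell counts spanning an order of magnitude)
    w = rng.exponential(1.0, n_cells)
    counts = rng.multinomial(n_cavities, w / w.sum())
    counts = np.clip(counts, lo, hi)
    # repair the total while conserving the per-cell bounds
    diff = n_cavities - int(counts.sum())
    while diff != 0:
        if diff > 0:
            slack = np.flatnonzero(counts < hi)
        else:
            slack = np.flatnonzero(counts > lo)
        pick = rng.choice(slack)
        counts[pick] += 1 if diff > 0 else -1
        diff += -1 if diff > 0 else 1
    return counts


def _sample_points_in_hexagon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a hexagon by rejection from its bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 8)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, xs, ys)
        out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
    return out[:n]


def _sample_cell_heights(
    n: int, target_mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal heights whose realised mean stays in the stated range.

    Heights are N(target_mean, sd) truncated to (0, 16] m; the cell sample is
    redrawn (bounded retries) until its mean lies within [4.8, 13.5] m so the
    generated field honours the per-cell summary the habitat is defined by.
    """
    lo, hi = CELL_MEAN_HEIGHT_RANGE
    for _ in range(1000):
        raw = rng.normal(target_mean, sd, size=4 * n)
        ok = raw[(raw > 0.1) & (raw <= MAX_CAVITY_HEIGHT)]
        if len(ok) < n:
            continue
        sample = ok[:n]
        if lo <= sample.mean() <= hi:
            return sample
    raise RuntimeError(
        f"could not realise a cell mean height near {target_mean} within "
        f"[{lo}, {hi}] m"
    )


def generate_synthetic_environment(
    n_cavities: int = 944,
    seed: int | np.random.Generator = 0,
    count_profile: Sequence[int] | None = None,
    height_means: Sequence[float] | None = None,
    height_sd: float = 1.5,
    grid: HexGrid | None = None,
) -> tuple[CavityField, HexGrid]:
    """Generate a synthetic cavity field matching the habitat's summary statistics.

    Per-cell cavity counts (default: symmetric multinomial repaired into
    [8, 92]) and per-cell mean heights (default: uniform in [4.8, 13.5] m)
    reproduce the published ranges; positions are uniform within each hexagon.
    The same seed reproduces the identical field bit-for-bit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = grid or build_hex_grid()
    if count_profile is not None:
        counts = np.asarray(count_profile, dtype=int)
        if len(counts) != grid.n_cells:
            raise ValueError("count_profile must have one entry per cell")
        lo, hi = CELL_COUNT_RANGE
        if counts.sum() != n_cavities or np.any(counts < lo) or np.any(counts > hi):
            raise ValueError(
                "count_profile must sum to n_cavities with entries in [8, 92]"
            )
    else:
        counts = _allocate_counts(n_cavities, grid.n_cells, rng)
    if height_means is None:
        # real cavity fields are bottom-heavy: most cells average 5-8 m with
        # a tall tail, so the habitat-wide mean stays below the heights that
        # roosting groups end up selecting.  A Beta(2, 5) profile over the
        # published per-cell range reproduces that shape.
        lo, hi = CELL_MEAN_HEIGHT_RANGE
        means = lo + (hi - lo) * rng.beta(1.5, 7.5, size=grid.n_cells)
    else:
        means = np.asarray(height_means, dtype=float)
        if len(means) != grid.n_cells:
            raise ValueError("height_means must have one entry per cell")

    xs, hs = [], []
    for c in range(grid.n_cells):
        pts = _sample_points_in_hexagon(grid.polygons[c], int(counts[c]), rng)
        heights = _sample_cell_heights(int(counts[c]), float(means[c]), height_sd, rng)
        xs.append(pts)
        hs.append(heights)
    xy = np.vstack(xs)
    height = np.concatenate(hs)
    field = CavityField(np.arange(len(xy)), xy, height)
    return field, grid


def load_cavities(path) -> CavityField:
    """Load a cavity table from CSV with columns id, x, y, z (height, m)."""
    df = pd.read_csv(path)
    required = {"id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cavity CSV missing columns: {sorted(missing)}")
    z = pd.to_numeric(df["z"], errors="coerce")
    if z.isna().any():
        row = int(np.argmax(z.isna().to_numpy()))
        raise ValueError(f"row {row}: non-numeric height")
    if (z <= 0).any():
        row = int(np.argmax((z <= 0).to_numpy()))
        raise ValueError(f"row {row}: height must be > 0, got {z.iloc[row]}")
    return CavityField(
        df["id"].to_numpy(np.int64),
        df[["x", "y"]].to_numpy(float),
        z.to_numpy(float),
    )


def save_cavities(field: CavityField, path) -> None:
    field.to_frame().to_csv(path, index=False)
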