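"""Randomly positioned hexagonal tiling of a cell point pattern.

Slides are subsampled by a regular hexagonal grid (default side 257 μm,
pointy-top orientation) whose offset is drawn uniformly over one lattice
period, so the tiling phase is random but reproducible under a fixed seed.
Each cell falls in exactly one hexagon (the hexagons are the Voronoi cells
of the hexagon centers); per-hexagon positive/negative counts for one
marker give a local positivity percentage. Hexagons with fewer than
``min_cells`` cells (default 50) are treated as insufficient sampling and
discarded from all downstream statistics, including adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cellmap import CellMap, marker_masks
from .errors import ConfigError

DEFAULT_SIDE_UM = 257.0
DEFAULT_MIN_CELLS = 50

#: Axial-coordinate steps to the 6 neighbors of a pointy-top hexagon.
AXIAL_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))
_HALF_NEIGHBORS = ((1, 0), (0, 1), (1, -1))


def hexagon_area(side: float) -> float:
    """Area of a regular hexagon with the given side length."""
    return 1.5 * np.sqrt(3.0) * side * side


@dataclass(frozen=True)
class HexGrid:
    """A pointy-top hexagonal lattice: side length, random offset, bounds (μm)."""

    side: float
    offset: tuple[float, float]
    bounds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ConfigError(f"hexagon side must be > 0, got {self.side}")

    # pointy-top axial basis: center(q, r) = offset + s*(√3(q+r/2), 1.5r)
    def centers(self, q: np.ndarray, r: np.ndarray) -> np.ndarray:
        s = self.side
        cx = self.offset[0] + s * np.sqrt(3.0) * (np.asarray(q) + np.asarray(r) / 2.0)
        cy = self.offset[1] + s * 1.5 * np.asarray(r)
        return np.stack([cx, cy], axis=-1)

    def to_axial(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points (μm) to the axial coordinates of their containing hexagon."""
        s = self.side
        dx = np.asarray(x, dtype=float) - self.offset[0]
        dy = np.asarray(y, dtype=float) - self.offset[1]
        qf = (np.sqrt(3.0) / 3.0 * dx - dy / 3.0) / s
        rf = (2.0 / 3.0 * dy) / s
        return _cube_round(qf, rf)


def _cube_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # round fractional cube coords to the nearest hexagon, fixing the axis
    # with the largest rounding error so q+r+s stays 0 (deterministic ties)
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)


def build_grid(
    bounds: tuple[float, float, float, float],
    side: float = DEFAULT_SIDE_UM,
    rng: np.random.Generator | None = None,
) -> HexGrid:
    """Build a randomly positioned grid covering ``bounds``.

    The offset is drawn uniformly over one lattice period (the fundamental
    domain spanned by the translations (√3·s, 0) and (√3·s/2, 1.5·s)), which
    makes the tiling phase uniform over all distinct placements.
    """
    if side <= 0:
        raise ConfigError(f"hexagon side must be > 0, got {side}")
    xmin, ymin, xmax, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ConfigError(f"degenerate bounds {bounds}")
    rng = np.random.default_rng() if rng is None else rng
    ox = float(rng.uniform(0.0, np.sqrt(3.0) * side))
    oy = float(rng.uniform(0.0, 1.5 * side))
    return HexGrid(side=side, offset=(ox, oy), bounds=tuple(map(float, bounds)))


@dataclass
class HexLattice:
    """Per-hexagon marker counts on one grid placement.

    ``table`` columns: q, r (axial), center_x_um, center_y_um, n_pos, n_neg,
    percent, retained. ``min_cells`` is None before filtering.
    """

    grid: HexGrid
    marker: str
    compartment: str
    table: pd.DataFrame
    min_cells: int | None = None

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    @property
    def percents(self) -> np.ndarray:
        """Positivity percentages of retained hexagons."""
        return self.retained["percent"].to_numpy(dtype=float)


def assign_cells(
    cellmap: CellMap,
    grid: HexGrid,
    marker: str,
    compartment: str = "tumor",
) -> HexLattice:
    """Count marker-positive/negative cells of one compartment per hexagon.

    Cells not evaluated for the marker are ignored; hexagons receiving no
    cells are omitted entirely.
    """
    sub = cellmap.compartment_cells(compartment)
    evaluated, positive = marker_masks(sub, marker)
    sub = sub[evaluated]
    positive = positive[evaluated]
    q, r = grid.to_axial(sub["x_um"].to_numpy(), sub["y_um"].to_numpy())
    df = pd.DataFrame({"q": q, "r": r, "pos": positive.astype(np.int64)})
    agg = df.groupby(["q", "r"], sort=True).agg(
        n_pos=("pos", "sum"), n=("pos", "size")
    )
    agg = agg.reset_index()
    agg["n_neg"] = agg["n"] - agg["n_pos"]
    total = agg["n_pos"] + agg["n_neg"]
    agg["percent"] = 100.0 * agg["n_pos"] / total
    centers = grid.centers(agg["q"].to_numpy(), agg["r"].to_numpy())
    agg["center_x_um"] = centers[:, 0] if len(agg) else []
    agg["center_y_um"] = centers[:, 1] if len(agg) else []
    agg["retained"] = True
    cols = ["q", "r", "center_x_um", "center_y_um", "n_pos", "n_neg", "percent", "retained"]
    return HexLattice(grid=grid, marker=marker, compartment=compartment,
                      table=agg[cols])


def filter_hexes(lattice: HexLattice, min_cells: int = DEFAULT_MIN_CELLS) -> HexLattice:
    """Flag hexagons with < ``min_cells`` cells as discarded."""
    if min_cells < 0:
        raise ConfigError("min_cells must be >= 0")
    table = lattice.table.copy()
    table["retained"] = (table["n_pos"] + table["n_neg"]) >= min_cells
    return replace(lattice, table=table, min_cells=min_cells)


def neighbor_pairs(lattice: HexLattice) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Unordered pairs of retained hexagons at axial distance 1.

    Discarded hexagons are excluded and do not bridge pairs: adjacency is
    evaluated on the retained set only.
    """
    ret = lattice.retained
    keys = set(zip(ret["q"].tolist(), ret["r"].tolist()))
    pairs = []
    for q, r in sorted(keys):
        for dq, dr in _HALF_NEIGHBORS:
            other = (q + dq, r + dr)
            if other in keys:
                pairs.append(((q, r), other))
    return pairs
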