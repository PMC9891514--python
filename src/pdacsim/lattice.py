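"""Geometry of the cell world.

Cell centres live in a rectangular domain; adjacency is the Delaunay
triangulation of the centres and each cell's footprint is its Voronoi
polygon clipped to the domain rectangle, so every cell "volume" W_i is
finite.  The initial tissue is a hexagonal packing of healthy cells; a
tumour is seeded by converting the centre-most cell.  As the tumour
approaches the populated boundary the domain is grown by appending whole
hexagonal rings of fresh healthy tissue.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, Voronoi

HEALTHY = 0
CANCER = 1
MCC = 2
DEAD = 3

CELL_TYPE_NAMES = {HEALTHY: "healthy", CANCER: "cancer", MCC: "mcc", DEAD: "dead"}

# encoding base for (i, j) edge keys; supports tissues up to ~2e9 cells
_KEY = np.int64(2) ** 31


@dataclasses.dataclass
class Tissue:
    """The agent world: cell records plus spring network geometry.

    Arrays are aligned by positional index; ``ids`` are stable labels that
    survive removals.  ``edges`` holds index pairs (i < j) from the current
    Delaunay triangulation, ``rest_length`` the spring equilibrium distance
    s_ij of each edge and ``rest_decrement`` the per-hour shrinkage applied
    to edges incident to a disintegrating dead cell.
    """

    ids: np.ndarray
    positions: np.ndarray
    cell_type: np.ndarray
    age: np.ndarray
    cooldown: np.ndarray
    maturity: np.ndarray
    disintegration_left: np.ndarray
    disintegration_total: np.ndarray
    voronoi_area: np.ndarray
    edges: np.ndarray
    rest_length: np.ndarray
    rest_decrement: np.ndarray
    bounds: tuple  # (xmin, xmax, ymin, ymax)
    sigma: float = 0.1728  # mm per model unit
    spacing: float = 1.0  # mature rest length s
    hex_origin: tuple = (0.0, 0.0)
    next_id: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def mask(self, *types: int) -> np.ndarray:
        return np.isin(self.cell_type, types)

    def count(self, *types: int) -> int:
        return int(self.mask(*types).sum())

    @property
    def tumour_mask(self) -> np.ndarray:
        return self.mask(CANCER, MCC)

    def neighbour_lists(self) -> list[np.ndarray]:
        """Adjacency lists (arrays of neighbour indices) from the edge set."""
        n = self.n_cells
        if len(self.edges) == 0:
            return [np.empty(0, dtype=np.int64) for _ in range(n)]
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        order = np.argsort(src, kind="stable")
        counts = np.bincount(src, minlength=n)
        return np.split(dst[order], np.cumsum(counts)[:-1])

    def copy(self) -> "Tissue":
        return Tissue(
            ids=self.ids.copy(),
            positions=self.positions.copy(),
            cell_type=self.cell_type.copy(),
            age=self.age.copy(),
            cooldown=self.cooldown.copy(),
            maturity=self.maturity.copy(),
            disintegration_left=self.disintegration_left.copy(),
            disintegration_total=self.disintegration_total.copy(),
            voronoi_area=self.voronoi_area.copy(),
            edges=self.edges.copy(),
            rest_length=self.rest_length.copy(),
            rest_decrement=self.rest_decrement.copy(),
            bounds=tuple(self.bounds),
            sigma=self.sigma,
            spacing=self.spacing,
            hex_origin=tuple(self.hex_origin),
            next_id=self.next_id,
        )


def _hex_points(n_rows: int, n_cols: int, spacing: float, origin=(0.0, 0.0)):
    """Hexagonal packing: alternate rows offset by spacing/2, pitch spacing*sqrt(3)/2."""
    ox, oy = origin
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    xx = ox + cols[None, :] * spacing + (rows[:, None] % 2) * (spacing / 2.0)
    yy = oy + rows[:, None] * (spacing * np.sqrt(3.0) / 2.0) + 0.0 * cols[None, :]
    return np.column_stack([xx.ravel(), yy.ravel()])


def init_hexagonal_tissue(n_rows: int, n_cols: int, spacing: float = 1.0,
                          sigma: float = 0.1728) -> Tissue:
    """Build an all-healthy tissue whose Voronoi cells tile hexagonally.

    Every interior cell has six Delaunay neighbours at distance ``spacing``
    and a regular-hexagon Voronoi cell of area sqrt(3)/2 * spacing**2.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if n_rows < 3 or n_cols < 3:
        raise ValueError(f"grid must be at least 3x3, got {n_rows}x{n_cols}")
    pts = _hex_points(n_rows, n_cols, spacing)
    n = len(pts)
    half = spacing / 2.0
    bounds = (
        pts[:, 0].min() - half,
        pts[:, 0].max() + half,
        pts[:, 1].min() - half * np.sqrt(3.0),
        pts[:, 1].max() + half * np.sqrt(3.0),
    )
    tissue = Tissue(
        ids=np.arange(n, dtype=np.int64),
        positions=pts.astype(float),
        cell_type=np.full(n, HEALTHY, dtype=np.int8),
        age=np.zeros(n, dtype=np.int64),
        cooldown=np.zeros(n, dtype=np.int64),
        maturity=np.ones(n, dtype=float),
        disintegration_left=np.zeros(n, dtype=np.int64),
        disintegration_total=np.zeros(n, dtype=np.int64),
        voronoi_area=np.zeros(n, dtype=float),
        edges=np.empty((0, 2), dtype=np.int64),
        rest_length=np.empty(0, dtype=float),
        rest_decrement=np.empty(0, dtype=float),
        bounds=bounds,
        sigma=sigma,
        spacing=spacing,
        hex_origin=(0.0, 0.0),
        next_id=n,
    )
    return rebuild_geometry(tissue)


def seed_tumour(tissue: Tissue) -> Tissue:
    """Convert the healthy cell nearest the domain centre into a cancer cell.

    Idempotent: if a cancer cell already exists the tissue is returned
    unchanged.  Distance ties resolve to the lowest cell id.
    """
    if tissue.n_cells == 0:
        raise ValueError("cannot seed a tumour in an empty tissue")
    if tissue.count(CANCER) > 0:
        return tissue
    xmin, xmax, ymin, ymax = tissue.bounds
    centre = np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])
    healthy = np.flatnonzero(tissue.mask(HEALTHY))
    if len(healthy) == 0:
        raise ValueError("no healthy cell available to seed")
    d = np.linalg.norm(tissue.positions[healthy] - centre, axis=1)
    # lowest id among distance ties
    best = d.min()
    ties = healthy[np.isclose(d, best)]
    chosen = ties[np.argmin(tissue.ids[ties])]
    tissue.cell_type[chosen] = CANCER
    return tissue


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    try:
        tri = Delaunay(points)
    except QhullError as exc:  # collinear / degenerate
        raise ValueError(f"degenerate cell configuration for triangulation: {exc}")
    s = tri.simplices.astype(np.int64)
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e.sort(axis=1)
    keys = np.unique(e[:, 0] * _KEY + e[:, 1])
    return np.column_stack([keys // _KEY, keys % _KEY])


def voronoi_areas(points: np.ndarray, bounds, subset=None,
                  mirror_margin: float | None = None) -> np.ndarray:
    """Areas of the Voronoi cells of ``points`` clipped to the rectangle.

    Clipping uses boundary mirroring: points near each side are reflected
    across it, which makes the rectangle an exact Voronoi boundary of the
    augmented set.  ``mirror_margin`` limits mirroring to points within that
    distance of a side (None mirrors everything, which is exact for any
    configuration).  ``subset`` restricts which cells' areas are evaluated
    (others return 0), which is cheap when only tumour-cell volumes W_i are
    needed.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    xmin, xmax, ymin, ymax = bounds
    mirrors = []
    for axis, lo_hi, val in ((0, "lo", xmin), (0, "hi", xmax),
                             (1, "lo", ymin), (1, "hi", ymax)):
        if mirror_margin is None:
            sel = np.ones(n, dtype=bool)
        elif lo_hi == "lo":
            sel = pts[:, axis] - val < mirror_margin
        else:
            sel = val - pts[:, axis] < mirror_margin
        m = pts[sel].copy()
        m[:, axis] = 2.0 * val - m[:, axis]
        mirrors.append(m)
    aug = np.vstack([pts] + mirrors)
    vor = Voronoi(aug)
    areas = np.zeros(n, dtype=float)
    vx = vor.vertices[:, 0]
    vy = vor.vertices[:, 1]
    regions = vor.regions
    point_region = vor.point_region
    idx = range(n) if subset is None else np.atleast_1d(subset)
    for i in idx:
        region = regions[point_region[i]]
        if -1 in region or len(region) < 3:
            # should not happen with sufficient mirroring
            continue
        x = vx[region]
        y = vy[region]
        # shoelace formula
        areas[i] = 0.5 * abs(
            np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])
            + x[-1] * y[0] - x[0] * y[-1])
    return areas


def voronoi_polygons(tissue: Tissue):
    """Clipped Voronoi polygons as shapely geometry, for plotting/snapshots."""
    import shapely.geometry as geom

    box = geom.box(*[tissue.bounds[k] for k in (0, 2, 1, 3)])
    xmin, xmax, ymin, ymax = tissue.bounds
    box = geom.box(xmin, ymin, xmax, ymax)
    pts = tissue.positions
    aug = np.vstack([
        pts,
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ])
    vor = Voronoi(aug)
    polys = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        poly = geom.Polygon(vor.vertices[region]).intersection(box)
        polys.append(poly)
    return polys


def _dead_fraction(tissue: Tissue) -> np.ndarray:
    """Remaining rest-length fraction per cell: 1 for living cells, the
    disintegration fraction for dead cells."""
    frac = np.ones(tissue.n_cells, dtype=float)
    dead = tissue.mask(DEAD)
    tot = np.maximum(tissue.disintegration_total[dead], 1)
    frac[dead] = tissue.disintegration_left[dead] / tot
    return frac


def rebuild_geometry(tissue: Tissue, compute_areas: bool = True,
                     area_subset=None) -> Tissue:
    """Recompute Delaunay edges and clipped Voronoi areas from positions.

    Rest lengths of persisting edges are carried over; a newly created edge
    (i, j) starts at s * min(maturity_i, maturity_j), further scaled by the
    disintegration fraction of a dead endpoint.  A fixed point when positions
    are unchanged.
    """
    if tissue.n_cells < 3:
        raise ValueError("need at least 3 cells to triangulate")
    new_edges = _delaunay_edges(tissue.positions)
    old_keys = tissue.edges[:, 0] * _KEY + tissue.edges[:, 1]
    order = np.argsort(old_keys)
    old_keys_sorted = old_keys[order]
    new_keys = new_edges[:, 0] * _KEY + new_edges[:, 1]
    pos = np.searchsorted(old_keys_sorted, new_keys)
    pos = np.clip(pos, 0, max(len(old_keys_sorted) - 1, 0))
    if len(old_keys_sorted):
        found = old_keys_sorted[pos] == new_keys
    else:
        found = np.zeros(len(new_keys), dtype=bool)

    rest = np.empty(len(new_edges), dtype=float)
    dec = np.zeros(len(new_edges), dtype=float)
    if found.any():
        src = order[pos[found]]
        rest[found] = tissue.rest_length[src]
        dec[found] = tissue.rest_decrement[src]
    if (~found).any():
        i = new_edges[~found, 0]
        j = new_edges[~found, 1]
        frac = _dead_fraction(tissue)
        m = np.minimum(tissue.maturity[i], tissue.maturity[j])
        rest[~found] = tissue.spacing * m * frac[i] * frac[j]
        # new edges to a dead cell shrink to zero by its removal time
        dead_i = tissue.cell_type[i] == DEAD
        dead_j = tissue.cell_type[j] == DEAD
        left = np.where(
            dead_i, tissue.disintegration_left[i],
            np.where(dead_j, tissue.disintegration_left[j], 0),
        )
        has_dead = left > 0
        nf = np.flatnonzero(~found)
        dec[nf[has_dead]] = rest[nf[has_dead]] / left[has_dead]
    tissue.edges = new_edges
    tissue.rest_length = rest
    tissue.rest_decrement = dec
    if compute_areas:
        tissue.voronoi_area = voronoi_areas(
            tissue.positions, tissue.bounds, subset=area_subset,
            mirror_margin=6.0 * tissue.spacing,
        )
    return tissue


def expand_domain(tissue: Tissue, margin: float = 10.0) -> Tissue:
    """Grow the populated rectangle when the tumour nears its boundary.

    If any cancer/MCC cell lies within ``margin`` model units of the bounds
    rectangle, hexagonally packed healthy cells are appended in a ring
    outside the current bounds (wide enough that no tumour cell remains
    within ``margin`` of the new boundary) and the bounds grow accordingly.
    Existing cells are untouched.  No-op otherwise.
    """
    tm = tissue.tumour_mask
    if not tm.any():
        return tissue
    xmin, xmax, ymin, ymax = tissue.bounds
    p = tissue.positions[tm]
    edge_dist = min(
        (p[:, 0] - xmin).min(), (xmax - p[:, 0]).min(),
        (p[:, 1] - ymin).min(), (ymax - p[:, 1]).min(),
    )
    if edge_dist >= margin:
        return tissue
    grow = margin + 2.0 * tissue.spacing - edge_dist
    s = tissue.spacing
    row_pitch = s * np.sqrt(3.0) / 2.0
    # regenerate the ideal hex lattice over the enlarged rectangle and keep
    # points falling outside the current bounds
    nxmin, nxmax = xmin - grow, xmax + grow
    nymin, nymax = ymin - grow, ymax + grow
    ox, oy = tissue.hex_origin
    r0 = int(np.floor((nymin - oy) / row_pitch)) - 1
    r1 = int(np.ceil((nymax - oy) / row_pitch)) + 1
    c0 = int(np.floor((nxmin - ox) / s)) - 1
    c1 = int(np.ceil((nxmax - ox) / s)) + 1
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    xx = ox + cols[None, :] * s + (rows[:, None] % 2) * (s / 2.0)
    yy = oy + rows[:, None] * row_pitch + 0.0 * cols[None, :]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside_new = (
        (pts[:, 0] >= nxmin) & (pts[:, 0] <= nxmax)
        & (pts[:, 1] >= nymin) & (pts[:, 1] <= nymax)
    )
    tol = 0.25 * s
    outside_old = (
        (pts[:, 0] < xmin + tol) | (pts[:, 0] > xmax - tol)
        | (pts[:, 1] < ymin + tol) | (pts[:, 1] > ymax - tol)
    )
    new_pts = pts[inside_new & outside_old]
    k = len(new_pts)
    if k == 0:
        return tissue
    tissue.ids = np.concatenate([tissue.ids, tissue.next_id + np.arange(k)])
    tissue.next_id += k
    tissue.positions = np.vstack([tissue.positions, new_pts])
    tissue.cell_type = np.concatenate([tissue.cell_type, np.full(k, HEALTHY, np.int8)])
    tissue.age = np.concatenate([tissue.age, np.zeros(k, np.int64)])
    tissue.cooldown = np.concatenate([tissue.cooldown, np.zeros(k, np.int64)])
    tissue.maturity = np.concatenate([tissue.maturity, np.ones(k)])
    tissue.disintegration_left = np.concatenate(
        [tissue.disintegration_left, np.zeros(k, np.int64)])
    tissue.disintegration_total = np.concatenate(
        [tissue.disintegration_total, np.zeros(k, np.int64)])
    tissue.voronoi_area = np.concatenate([tissue.voronoi_area, np.zeros(k)])
    tissue.bounds = (nxmin, nxmax, nymin, nymax)
    return rebuild_geometry(tissue, compute_areas=False)


def remove_cells(tissue: Tissue, indices: np.ndarray) -> Tissue:
    """Delete cell records (disintegrated dead cells), leaving empty space.

    Edges incident to removed cells are dropped and the remainder reindexed;
    a geometry rebuild is expected afterwards.
    """
    if len(indices) == 0:
        return tissue
    keep = np.ones(tissue.n_cells, dtype=bool)
    keep[indices] = False
    remap = -np.ones(tissue.n_cells, dtype=np.int64)
    remap[keep] = np.arange(keep.sum())
    for name in ("ids", "positions", "cell_type", "age", "cooldown", "maturity",
                 "disintegration_left", "disintegration_total", "voronoi_area"):
        setattr(tissue, name, getattr(tissue, name)[keep])
    e_keep = keep[tissue.edges[:, 0]] & keep[tissue.edges[:, 1]]
    tissue.edges = remap[tissue.edges[e_keep]]
    tissue.rest_length = tissue.rest_length[e_keep]
    tissue.rest_decrement = tissue.rest_decrement[e_keep]
    return tissue


def write_snapshot(tissue: Tissue, time_h: float, path, append: bool = False) -> None:
    """Write a cell snapshot CSV: (time_h, id, x, y, cell_type, voronoi_area)."""
    area = voronoi_areas(tissue.positions, tissue.bounds,
                         mirror_margin=6.0 * tissue.spacing)
    df = pd.DataFrame({
        "time_h": time_h,
        "id": tissue.ids,
        "x": tissue.positions[:, 0],
        "y": tissue.positions[:, 1],
        "cell_type": [CELL_TYPE_NAMES[t] for t in tissue.cell_type],
        "voronoi_area": area,
    })
    mode = "a" if append else "w"
    df.to_csv(path, mode=mode, header=not append, index=False)
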