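"""Planar geometric primitives: cell boundary polygons, curvature, normals,
and the shared-vertex hexagonal tissue mesh.

Conventions
-----------
All coordinates are in micrometres on a 2-D plane. The anterior-posterior
(A-P) axis runs along +x and the dorsal-ventral (D-V) axis along +y unless an
:class:`AxisFrame` says otherwise. Cell outlines are simple polygons stored
counter-clockwise; the closing edge (last vertex back to the first) is
implicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BoundaryPolygon",
    "AxisFrame",
    "TissueMesh",
    "polygon_measures",
    "discrete_curvature",
    "outward_normal",
    "hexagonal_tiling",
    "read_trajectory_jsonl",
    "write_trajectory_jsonl",
    "read_trajectory_csv",
    "write_trajectory_csv",
]


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class BoundaryPolygon:
    """Closed 2-D cell outline at one time point.

    Parameters
    ----------
    vertices : (n, 2) array
        Ordered vertex positions in micrometres. Counter-clockwise
        orientation is enforced at construction; clockwise input is
        rejected rather than silently flipped so that upstream sign
        errors surface early (use :meth:`ensure_ccw` to repair).
    frame_time : float
        Acquisition / simulation time in minutes.
    cell_id : str
        Identifier of the cell this outline belongs to.
    """

    vertices: np.ndarray
    frame_time: float = 0.0
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("polygon needs an (n >= 3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise GeometryError("polygon vertices must be finite")
        seg = np.roll(v, -1, axis=0) - v
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) <= 0.0):
            raise GeometryError("duplicated consecutive vertices")
        if _signed_area(v) <= 0.0:
            raise GeometryError(
                "polygon must be counter-clockwise with positive area"
            )
        self.vertices = v

    @classmethod
    def ensure_ccw(cls, vertices, frame_time: float = 0.0, cell_id: str = "cell"):
        """Build a polygon, flipping vertex order if it arrives clockwise."""
        v = np.asarray(vertices, dtype=float)
        if v.ndim == 2 and v.shape[0] >= 3 and _signed_area(v) < 0.0:
            v = v[::-1]
        return cls(v, frame_time=frame_time, cell_id=cell_id)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])


@dataclass(frozen=True)
class AxisFrame:
    """Orthonormal tissue frame: A-P unit vector and D-V unit vector."""

    ap_unit: tuple[float, float] = (1.0, 0.0)
    dv_unit: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        ap = np.asarray(self.ap_unit, dtype=float)
        dv = np.asarray(self.dv_unit, dtype=float)
        if abs(np.linalg.norm(ap) - 1.0) > 1e-9 or abs(np.linalg.norm(dv) - 1.0) > 1e-9:
            raise GeometryError("axis vectors must be unit length")
        if abs(float(ap @ dv)) > 1e-9:
            raise GeometryError("axis vectors must be orthogonal")
        object.__setattr__(self, "ap_unit", (float(ap[0]), float(ap[1])))
        object.__setattr__(self, "dv_unit", (float(dv[0]), float(dv[1])))

    @property
    def ap(self) -> np.ndarray:
        return np.asarray(self.ap_unit)

    @property
    def dv(self) -> np.ndarray:
        return np.asarray(self.dv_unit)


def polygon_measures(poly: BoundaryPolygon) -> dict:
    """Basic morphometrics of a closed outline.

    Returns a dict with ``area`` (shoelace, um^2), ``perimeter`` (um),
    ``equivdiameter`` (mean centroid-to-vertex distance, um) and
    ``centroid`` (area centroid, um).
    """
    v = poly.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    if area <= 1e-12:
        raise GeometryError("degenerate polygon: zero area")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * area)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * area)
    perimeter = float(np.sum(np.hypot(xn - x, yn - y)))
    equivdiameter = float(np.mean(np.hypot(x - cx, y - cy)))
    return {
        "area": area,
        "perimeter": perimeter,
        "equivdiameter": equivdiameter,
        "centroid": np.array([cx, cy]),
    }


def _smooth_closed(v: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of vertex positions (window must be odd)."""
    if window <= 1:
        return v
    half = window // 2
    padded = np.concatenate([v[-half:], v, v[:half]], axis=0)
    kernel = np.ones(window) / window
    out = np.empty_like(v)
    for k in (0, 1):
        out[:, k] = np.convolve(padded[:, k], kernel, mode="valid")
    return out


def discrete_curvature(poly: BoundaryPolygon, smooth_window: int = 1) -> np.ndarray:
    """Signed per-vertex curvature (1/um) of a closed outline.

    Positive on convex (outward-bulging) arcs of a counter-clockwise
    polygon. Positions are window-averaged first, then the curvature at
    each vertex is that of the circle through the vertex and its two
    smoothed neighbours (Menger curvature, signed by the turn direction).
    """
    if poly.n_vertices < 5:
        raise GeometryError("curvature needs >= 5 vertices")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise GeometryError("smooth_window must be odd and >= 1")
    if smooth_window >= poly.n_vertices:
        raise GeometryError("smooth_window must be smaller than vertex count")
    v = _smooth_closed(poly.vertices, smooth_window)
    prv = np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0)
    a = v - prv
    b = nxt - v
    chord = nxt - prv
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    denom = (
        np.hypot(a[:, 0], a[:, 1])
        * np.hypot(b[:, 0], b[:, 1])
        * np.hypot(chord[:, 0], chord[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0.0, 2.0 * cross / denom, 0.0)
    return kappa


def outward_normal(poly: BoundaryPolygon, vertex_index: int | None = None) -> np.ndarray:
    """Unit outward normal(s) of the boundary.

    With ``vertex_index`` given, returns the (2,) normal at that vertex;
    otherwise the full (n, 2) array. The normal is perpendicular to the
    local tangent (central difference of neighbours) and points away from
    the interior of the counter-clockwise polygon.
    """
    v = poly.vertices
    tangent = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    # rotate CCW tangent by -90 deg -> outward
    normal = np.stack([tangent[:, 1], -tangent[:, 0]], axis=1)
    norms = np.hypot(normal[:, 0], normal[:, 1])
    norms[norms == 0.0] = 1.0
    normal /= norms[:, None]
    if vertex_index is not None:
        return normal[int(vertex_index)]
    return normal


# ---------------------------------------------------------------------------
# Tissue mesh


@dataclass
class TissueMesh:
    """Cells as ordered loops over a shared pool of boundary vertices.

    ``vertex_pool`` holds every boundary vertex once; an edge between two
    neighbouring cells references the same pool indices from both loops
    (the discrete adhesion-cluster picture). Each vertex also carries a
    substrate ``anchor`` position used by the adhesion force.
    """

    vertex_pool: np.ndarray
    cells: list[np.ndarray]
    anchors: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertex_pool = np.asarray(self.vertex_pool, dtype=float)
        self.anchors = np.asarray(self.anchors, dtype=float)
        self.cells = [np.asarray(c, dtype=int) for c in self.cells]
        if not self.cell_ids:
            self.cell_ids = [f"c{i:03d}" for i in range(len(self.cells))]

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_pool.shape[0])

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_polygon(self, i: int, frame_time: float = 0.0) -> BoundaryPolygon:
        return BoundaryPolygon(
            self.vertex_pool[self.cells[i]],
            frame_time=frame_time,
            cell_id=self.cell_ids[i],
        )

    @property
    def adjacency(self) -> dict[int, list[int]]:
        """Vertex pool index -> list of cell indices referencing it."""
        adj: dict[int, list[int]] = {}
        for ci, loop in enumerate(self.cells):
            for vi in loop:
                adj.setdefault(int(vi), []).append(ci)
        return adj

    def validate(self) -> None:
        """Raise GeometryError if any invariant is broken."""
        for i in range(self.n_cells):
            self.cell_polygon(i)
        if self.anchors.shape != self.vertex_pool.shape:
            raise GeometryError("anchors must mirror the vertex pool shape")

    def copy(self) -> "TissueMesh":
        return TissueMesh(
            self.vertex_pool.copy(),
            [c.copy() for c in self.cells],
            self.anchors.copy(),
            list(self.cell_ids),
        )


def hexagonal_tiling(
    n_rows: int, n_cols: int, edge_len: float, verts_per_edge: int = 1
) -> TissueMesh:
    """Tightly packed pointy-top hexagons with shared, subdivided edges.

    Each of the six hexagon edges carries ``verts_per_edge`` vertices
    (the corner plus ``verts_per_edge - 1`` interior subdivision points),
    so every cell loop has ``6 * verts_per_edge`` vertices. Vertices on
    interior edges are pooled, so neighbouring cells reference identical
    indices. Substrate anchors start at the vertex positions.
    """
    if n_rows < 1 or n_cols < 1 or verts_per_edge < 1 or edge_len <= 0:
        raise GeometryError("tiling sizes must be positive")
    a = float(edge_len)
    dx = np.sqrt(3.0) * a
    dy = 1.5 * a
    # pointy-top corners, CCW starting at angle -90 deg (bottom tip)
    angles = np.deg2rad(np.arange(-90.0, 270.0, 60.0))
    corners = np.stack([a * np.cos(angles), a * np.sin(angles)], axis=1)

    pool: list[np.ndarray] = []
    index_of: dict[tuple[int, int], int] = {}

    def pooled(p: np.ndarray) -> int:
        key = (int(round(p[0] * 1e6)), int(round(p[1] * 1e6)))
        idx = index_of.get(key)
        if idx is None:
            idx = len(pool)
            index_of[key] = idx
            pool.append(p)
        return idx

    cells: list[np.ndarray] = []
    ids: list[str] = []
    for r in range(n_rows):
        for c in range(n_cols):
            cx = c * dx + (dx / 2.0 if r % 2 else 0.0)
            cy = r * dy
            loop: list[int] = []
            for k in range(6):
                p0 = corners[k] + (cx, cy)
                p1 = corners[(k + 1) % 6] + (cx, cy)
                for s in range(verts_per_edge):
                    t = s / verts_per_edge
                    loop.append(pooled(p0 + t * (p1 - p0)))
            cells.append(np.asarray(loop, dtype=int))
            ids.append(f"r{r}c{c}")
    vertex_pool = np.asarray(pool, dtype=float)
    mesh = TissueMesh(vertex_pool, cells, vertex_pool.copy(), ids)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Trajectory I/O


def write_trajectory_jsonl(path, polygons: list[BoundaryPolygon]) -> None:
    """One JSON record per cell per frame: cell_id, time_min, vertices."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in polygons:
            rec = {
                "cell_id": p.cell_id,
                "time_min": float(p.frame_time),
                "vertices": [[float(x), float(y)] for x, y in p.vertices],
            }
            fh.write(json.dumps(rec) + "\n")


def read_trajectory_jsonl(path) -> list[BoundaryPolygon]:
    out: list[BoundaryPolygon] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                out.append(
                    BoundaryPolygon(
                        np.asarray(rec["vertices"], dtype=float),
                        frame_time=float(rec["time_min"]),
                        cell_id=str(rec["cell_id"]),
                    )
                )
            except (KeyError, ValueError, GeometryError) as exc:
                raise ValueError(f"malformed trajectory record at line {lineno}: {exc}")
    if not out:
        raise ValueError(f"no records in trajectory file {path}")
    return out


def write_trajectory_csv(path, polygons: list[BoundaryPolygon]) -> None:
    rows = []
    for p in polygons:
        for i, (x, y) in enumerate(p.vertices):
            rows.append((p.cell_id, float(p.frame_time), i, float(x), float(y)))
    df = pd.DataFrame(rows, columns=["cell_id", "time_min", "vertex_index", "x", "y"])
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> list[BoundaryPolygon]:
    df = pd.read_csv(path)
    required = {"cell_id", "time_min", "vertex_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    out = []
    for (cid, t), grp in df.groupby(["cell_id", "time_min"], sort=True):
        grp = grp.sort_values("vertex_index")
        out.append(
            BoundaryPolygon(
                grp[["x", "y"]].to_numpy(float), frame_time=float(t), cell_id=str(cid)
            )
        )
    if not out:
        raise ValueError(f"no records in trajectory file {path}")
    return out
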