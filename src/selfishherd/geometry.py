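"""Cutoff-bounded Voronoi tessellation: domains of danger (DOD).

Under the selfish-herd hypothesis the predation risk of an individual is
proportional to the area of its Voronoi cell, the *domain of danger*.  To
keep peripheral cells finite each cell is intersected with a disk of cutoff
radius ``delta`` centred on its own agent, so an isolated agent has the
maximum possible area ``A_max = pi * delta**2``.

The computation is exact (no polygonal circle approximation): each agent's
cell is built by clipping a bounding square with the perpendicular-bisector
half-planes of every neighbour closer than ``2*delta``, and the area of the
resulting convex polygon intersected with the cutoff disk is evaluated in
closed form via Green's theorem (triangle pieces inside the disk, circular
sectors outside).  This is robust for any point configuration, including
collinear ones that break a general-position Voronoi construction.

All lengths are in units of the body diameter sigma; areas in sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointSet2D",
    "DODResult",
    "DegenerateTessellationError",
    "compute_dod",
    "nearest_neighbor_distances",
]

#: absolute geometric tolerance for polygon clipping, in sigma
GEOM_TOL = 1e-9

#: pairwise distance below which a configuration counts as coincident
COINCIDENCE_TOL = 1e-9


class DegenerateTessellationError(ValueError):
    """Raised for coincident points, for which the tessellation is undefined."""


@dataclass(frozen=True)
class PointSet2D:
    """A finite set of agent positions on the plane (units sigma)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("positions must be a non-empty (N, 2) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class DODResult:
    """Per-agent DOD areas, cutoff-Voronoi adjacency, and nearest-neighbour distances."""

    areas: np.ndarray                      # (N,) areas A_i, sigma^2
    adjacency: np.ndarray                  # (N, N) symmetric bool, zero diagonal
    nn_distance: np.ndarray                # (N,) distance to nearest other agent; inf for N=1
    delta: float = field(default=10.0)     # cutoff radius used

    @property
    def a_max(self) -> float:
        return float(np.pi * self.delta**2)

    def neighbor_sets(self) -> list[set[int]]:
        """Adjacency as per-agent index sets (used by neighbour-persistence analysis)."""
        return [set(np.flatnonzero(row)) for row in self.adjacency]


def nearest_neighbor_distances(points: PointSet2D | np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each agent to its nearest other agent.

    Requires at least two points.
    """
    pos = points.positions if isinstance(points, PointSet2D) else np.asarray(points, float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("nearest_neighbor_distances requires at least 2 points")
    tree = cKDTree(pos)
    d, _ = tree.query(pos, k=2)
    return d[:, 1].astype(float)


def _clip_polygon_halfplane(verts, labels, point, normal, new_label):
    """Sutherland–Hodgman clip of a convex polygon to {x : (x - point)·normal <= 0}.

    ``labels[k]`` identifies the generator of edge (verts[k], verts[k+1]); the edge
    created along the clipping line gets ``new_label``.  Returns (verts, labels) or
    (None, None) when the polygon vanishes.
    """
    d = (verts - point) @ normal
    inside = d <= GEOM_TOL
    if inside.all():
        return verts, labels
    if not inside.any():
        return None, None
    m = len(verts)
    out_v: list[np.ndarray] = []
    out_l: list[object] = []
    for k in range(m):
        k2 = (k + 1) % m
        a, b = verts[k], verts[k2]
        da, db = d[k], d[k2]
        if inside[k]:
            out_v.append(a)
            out_l.append(labels[k])
            if not inside[k2]:
                t = da / (da - db)
                out_v.append(a + t * (b - a))
                out_l.append(new_label)      # edge leaving along the clip line
        elif inside[k2]:
            t = da / (da - db)
            out_v.append(a + t * (b - a))
            out_l.append(labels[k])          # remainder of the original edge
    if len(out_v) < 3:
        return None, None
    return np.asarray(out_v), out_l


def _circle_polygon_area(verts: np.ndarray, radius: float) -> float:
    """Exact area of (convex polygon) ∩ (disk of ``radius`` centred at the origin).

    The polygon is assumed to contain the origin and be counter-clockwise, which
    holds for a Voronoi cell around its own generator.  Green's theorem over the
    boundary: segment pieces inside the disk contribute triangle areas with the
    origin, pieces outside contribute circular sectors.
    """
    r2 = radius * radius
    area = 0.0
    m = len(verts)
    for k in range(m):
        p = verts[k]
        q = verts[(k + 1) % m]
        dp = p @ p
        dq = q @ q
        in_p = dp <= r2
        in_q = dq <= r2
        if in_p and in_q:
            area += 0.5 * (p[0] * q[1] - p[1] * q[0])
            continue
        # intersection parameters of |p + t (q - p)| = radius on t in [0, 1]
        e = q - p
        aa = e @ e
        bb = 2.0 * (p @ e)
        cc = dp - r2
        disc = bb * bb - 4.0 * aa * cc
        ts: list[float] = []
        if disc > 0.0 and aa > 0.0:
            sq = np.sqrt(disc)
            for t in ((-bb - sq) / (2 * aa), (-bb + sq) / (2 * aa)):
                if 0.0 < t < 1.0:
                    ts.append(t)
        pieces = [p] + [p + t * e for t in sorted(ts)] + [q]
        for j in range(len(pieces) - 1):
            a, b = pieces[j], pieces[j + 1]
            mid = 0.5 * (a + b)
            if mid @ mid <= r2:
                area += 0.5 * (a[0] * b[1] - a[1] * b[0])
            else:
                ang = np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b)
                area += 0.5 * r2 * ang
    return float(area)


def _segment_in_disk_interval(a, b, center, radius):
    """Parameter interval [t0, t1] of segment a->b lying inside the given disk, or None."""
    e = b - a
    f = a - center
    aa = e @ e
    if aa < GEOM_TOL**2:
        return None
    bb = 2.0 * (f @ e)
    cc = f @ f - radius * radius
    disc = bb * bb - 4.0 * aa * cc
    if disc <= 0.0:
        return None
    sq = np.sqrt(disc)
    t0 = max(0.0, (-bb - sq) / (2 * aa))
    t1 = min(1.0, (-bb + sq) / (2 * aa))
    if t1 <= t0:
        return None
    return t0, t1


def compute_dod(
    points: PointSet2D | np.ndarray, delta: float = 10.0
) -> DODResult:
    """Cutoff-bounded Voronoi tessellation of a point set.

    Parameters
    ----------
    points
        Agent positions, shape (N, 2), units sigma.
    delta
        Cutoff radius in sigma; each cell is intersected with the disk of
        radius ``delta`` around its own agent, so ``A_max = pi * delta**2``.

    Returns
    -------
    DODResult
        Exact per-agent areas, the cutoff-Voronoi adjacency (pairs whose shared
        edge has positive length inside *both* cutoff disks), and exact
        nearest-neighbour distances.
    """
    if not isinstance(points, PointSet2D):
        points = PointSet2D(np.asarray(points, float))
    if delta <= 0:
        raise ValueError("delta must be positive")
    pos = points.positions
    n = points.n

    areas = np.empty(n)
    adjacency = np.zeros((n, n), dtype=bool)

    if n == 1:
        areas[0] = np.pi * delta**2
        return DODResult(areas, adjacency, np.full(1, np.inf), delta)

    nn = nearest_neighbor_distances(points)
    if np.min(nn) < COINCIDENCE_TOL:
        raise DegenerateTessellationError(
            "coincident points: pairwise distance below 1e-9 sigma"
        )

    tree = cKDTree(pos)
    # only neighbours closer than 2*delta can clip the disk or share an in-range edge
    neighbor_lists = tree.query_ball_point(pos, 2.0 * delta)

    half = 1.5 * delta  # bounding square comfortably containing the cutoff disk
    square = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])

    for i in range(n):
        center = pos[i]
        verts = square + center
        labels: list[object] = [None] * 4
        for j in sorted(neighbor_lists[i], key=lambda j: np.hypot(*(pos[j] - center))):
            if j == i:
                continue
            mid = 0.5 * (center + pos[j])
            normal = pos[j] - center
            normal = normal / np.linalg.norm(normal)
            verts, labels = _clip_polygon_halfplane(verts, labels, mid, normal, j)
            if verts is None:  # cannot happen: the cell always contains its generator
                raise DegenerateTessellationError("cell vanished during clipping")
        areas[i] = _circle_polygon_area(verts - center, delta)
        # adjacency: shared bisector edge with positive length inside both cutoff disks
        m = len(verts)
        for k in range(m):
            j = labels[k]
            if j is None or adjacency[i, j]:
                continue
            a, b = verts[k], verts[(k + 1) % m]
            if np.hypot(*(b - a)) < GEOM_TOL:
                continue
            iv_i = _segment_in_disk_interval(a, b, center, delta)
            if iv_i is None:
                continue
            iv_j = _segment_in_disk_interval(a, b, pos[j], delta)
            if iv_j is None:
                continue
            if min(iv_i[1], iv_j[1]) - max(iv_i[0], iv_j[0]) > GEOM_TOL:
                adjacency[i, j] = adjacency[j, i] = True

    return DODResult(areas, adjacency, nn, delta)
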