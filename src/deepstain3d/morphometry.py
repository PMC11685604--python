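"""Morphometry of traced filaments and trees.

Implements the path metrics used to characterize podocyte-to-capsule
microfilaments crossing the Bowman space — path length d_path, displacement
d_fil, minimal (radial) distance d_min, tortuosity d_path/d_fil, skewness
d_fil/d_min, take-off angle against the distance-field gradient, and
reacher/stayer classification — together with geodesic distances constrained
to a voxelized surface, nearest-neighbor geodesic statistics of attachment
points, and tree morphometrics (Sholl intersection profiles, Horton–Strahler
order) for traced inclusions.

Coordinates are physical (z, y, x) in µm throughout.  Undefined metrics
(zero denominators, zero gradients) are reported as NaN, never ±inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.stats import pearsonr, spearmanr

from .grid import (
    DistanceField,
    MaskVolume,
    Spacing,
    VolumeGrid,
    distance_transform,
    gaussian_gradient,
    surface_voxels,
)

__all__ = [
    "TracedPath",
    "TracedTree",
    "PathMetrics",
    "SurfaceGraph",
    "path_length",
    "path_displacement",
    "minimal_distance",
    "tortuosity_skewness",
    "takeoff_angle",
    "classify_reacher",
    "compute_path_metrics",
    "geodesic_distance",
    "nn_geodesic_stats",
    "sholl_analysis",
    "horton_strahler",
    "read_swc_path",
    "read_swc_tree",
    "write_swc",
]


@dataclass
class TracedPath:
    """Ordered 3D polyline in (z, y, x) µm; at least two distinct points."""

    points: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (z, y, x) µm")
        if len(self.points) >= 2:
            seg = np.diff(self.points, axis=0)
            if np.any(np.all(seg == 0, axis=1)):
                raise ValueError("consecutive path points must be distinct")

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class TracedTree:
    """Rooted tree of 3D nodes.

    ``nodes`` maps node id -> (z, y, x) µm position; ``parents`` maps node
    id -> parent id (root maps to None).  Exactly one root; parent links must
    form a single connected acyclic structure.
    """

    nodes: dict[int, np.ndarray]
    parents: dict[int, Optional[int]]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        for n, p in self.parents.items():
            if p is not None and p not in self.nodes:
                raise ValueError(f"node {n} has unknown parent {p}")
        # cycle/connectivity check: walk every node up to the root
        for n in self.nodes:
            seen = set()
            cur: Optional[int] = n
            while cur is not None:
                if cur in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(cur)
                cur = self.parents[cur]
            if self._root not in seen:
                raise ValueError("tree is not connected")

    @property
    def root(self) -> int:
        return self._root

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n: [] for n in self.nodes}
        for n, p in self.parents.items():
            if p is not None:
                ch[p].append(n)
        return ch

    def edges(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parent_pos, child_pos) pairs for every non-root node."""
        return [
            (self.nodes[p], self.nodes[n]) for n, p in self.parents.items() if p is not None
        ]


@dataclass
class PathMetrics:
    """Per-filament morphometrics; NaN marks undefined quantities."""

    d_path: float
    d_fil: float
    d_min: float
    tortuosity: float
    skewness: float
    takeoff_angle: float
    is_reacher: Optional[bool] = None


# ---------------------------------------------------------------------------
# scalar path metrics
# ---------------------------------------------------------------------------


def path_length(path: TracedPath) -> float:
    """Arc length of the polyline: sum of Euclidean segment lengths (µm)."""
    if len(path.points) < 2:
        raise ValueError("path_length needs at least 2 points")
    return float(np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum())


def path_displacement(path: TracedPath) -> float:
    """Straight-line start-to-end distance (µm)."""
    if len(path.points) < 2:
        raise ValueError("path_displacement needs at least 2 points")
    return float(np.linalg.norm(path.end - path.start))


def minimal_distance(path: TracedPath, dist_field: DistanceField, interpolate: bool = False) -> float:
    """|field(end) − field(start)|: the radial extent traversed in the field."""
    return abs(
        dist_field.value_at(path.end, interpolate=interpolate)
        - dist_field.value_at(path.start, interpolate=interpolate)
    )


def tortuosity_skewness(d_path: float, d_fil: float, d_min: float) -> tuple[float, float]:
    """(d_path/d_fil, d_fil/d_min); NaN where the denominator vanishes."""
    tort = d_path / d_fil if d_fil > 0 else math.nan
    skew = d_fil / d_min if d_min > 0 else math.nan
    return tort, skew


def takeoff_angle(
    path: TracedPath, dist_field: DistanceField, sigma: float = 2.0
) -> float:
    """Angle (degrees, [0, 180]) between the distance-field gradient at the
    path start and the unit displacement vector.

    The gradient is a Gaussian derivative of the field at scale ``sigma`` µm
    (voxelized distance fields have non-smooth one-voxel differences).
    Returns NaN when the gradient norm at the start is numerically zero.
    """
    grad = gaussian_gradient(VolumeGrid(dist_field.data, dist_field.spacing), sigma)
    grid = VolumeGrid(dist_field.data, dist_field.spacing)
    iz, iy, ix = grid.coords_to_index(path.start)
    g = grad[:, iz, iy, ix]
    gn = np.linalg.norm(g)
    disp = path.end - path.start
    dn = np.linalg.norm(disp)
    if gn < 1e-12 or dn == 0:
        return math.nan
    cosang = float(np.clip(np.dot(g / gn, disp / dn), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def classify_reacher(path: TracedPath, pec_mask: MaskVolume, tolerance: float = 0.0) -> bool:
    """True iff the path end lies within ``tolerance`` µm of the capsule mask."""
    dist = distance_transform(pec_mask)
    return dist.value_at(path.end) <= tolerance + 1e-9


def compute_path_metrics(
    path: TracedPath,
    dist_field: DistanceField,
    pec_mask: Optional[MaskVolume] = None,
    tolerance: float = 0.0,
    gradient_sigma: float = 2.0,
) -> PathMetrics:
    """All scalar morphometrics of one filament in a single pass."""
    d_p = path_length(path)
    d_f = path_displacement(path)
    d_m = minimal_distance(path, dist_field)
    tort, skew = tortuosity_skewness(d_p, d_f, d_m)
    angle = takeoff_angle(path, dist_field, sigma=gradient_sigma)
    reach = classify_reacher(path, pec_mask, tolerance) if pec_mask is not None else None
    return PathMetrics(d_p, d_f, d_m, tort, skew, angle, reach)


# ---------------------------------------------------------------------------
# voxel-surface geodesics
# ---------------------------------------------------------------------------


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return np.array(offs)


class SurfaceGraph:
    """Weighted graph over the surface voxels of a mask.

    Nodes are the foreground voxels with at least one background face-neighbor
    (the outer shell); edges join voxels that are neighbors under the chosen
    connectivity, weighted by the physical Euclidean step between their
    centers.  Geodesic distance between two surface voxels is the shortest
    path length on this graph.
    """

    def __init__(self, coords: np.ndarray, spacing: Spacing, connectivity: int = 26):
        self.coords = np.asarray(coords, dtype=int)  # (n, 3) voxel indices
        self.spacing = spacing
        self.connectivity = connectivity
        self._index = {tuple(c): i for i, c in enumerate(self.coords)}
        self._adj = self._build_adjacency()

    @classmethod
    def from_mask(cls, mask: MaskVolume, connectivity: int = 26) -> "SurfaceGraph":
        surf = surface_voxels(mask)
        coords = np.argwhere(surf.data)
        if coords.size == 0:
            raise ValueError("mask has no surface voxels")
        return cls(coords, mask.spacing, connectivity)

    def _build_adjacency(self) -> sp.csr_matrix:
        n = len(self.coords)
        offs = _neighbor_offsets(self.connectivity)
        # keep only one of each antipodal pair; csr made symmetric below
        half = offs[: len(offs) // 2]
        rows, cols, weights = [], [], []
        spc = np.asarray(self.spacing)
        for off in half:
            w = float(np.linalg.norm(off * spc))
            shifted = self.coords + off
            for i, c in enumerate(map(tuple, shifted)):
                j = self._index.get(c)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    weights.append(w)
        adj = sp.csr_matrix((weights, (rows, cols)), shape=(n, n))
        return adj + adj.T

    def __len__(self) -> int:
        return len(self.coords)

    def node_of(self, voxel) -> int:
        """Graph index of a surface voxel (z, y, x) index triple."""
        key = tuple(int(v) for v in voxel)
        if key not in self._index:
            raise ValueError(f"voxel {key} is not on the surface")
        return self._index[key]

    def nearest_node(self, point_um) -> int:
        """Graph index of the surface voxel nearest a physical µm point."""
        p_vox = np.asarray(point_um, dtype=float) / np.asarray(self.spacing)
        d2 = np.sum((self.coords - p_vox) ** 2 * np.asarray(self.spacing) ** 2, axis=1)
        return int(np.argmin(d2))

    def distances_from(self, sources: Sequence[int]) -> np.ndarray:
        """Dijkstra distance matrix (len(sources), n_nodes); inf = unreachable."""
        return _csgraph_dijkstra(self._adj, directed=False, indices=list(sources))


def geodesic_distance(surface: SurfaceGraph, p, q) -> float:
    """Shortest on-surface path length (µm) between surface voxels p and q.

    Raises if either voxel is off the surface; returns inf when the two lie
    in disconnected surface components.
    """
    i, j = surface.node_of(p), surface.node_of(q)
    d = surface.distances_from([i])[0, j]
    return float(d)


def nn_geodesic_stats(
    attachment_points: np.ndarray,
    surface: SurfaceGraph,
    path_lengths: Optional[Sequence[float]] = None,
    snap: bool = True,
) -> pd.DataFrame:
    """Nearest-neighbor geodesic distance for each attachment point.

    ``attachment_points`` are physical (z, y, x) µm coordinates (snapped to
    the nearest surface voxel when ``snap``) or voxel triples otherwise.
    When ``path_lengths`` is given, the returned frame carries
    ``.attrs['pearson_r']`` and ``.attrs['spearman_r']`` — the correlation of
    path length against nearest-neighbor geodesic distance.
    """
    pts = np.asarray(attachment_points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 attachment points")
    if snap:
        nodes = [surface.nearest_node(p) for p in pts]
    else:
        nodes = [surface.node_of(p) for p in pts]
    dmat = surface.distances_from(nodes)[:, nodes]
    np.fill_diagonal(dmat, np.inf)
    nn = dmat.min(axis=1)
    out = pd.DataFrame({"node": nodes, "nn_geodesic": nn})
    if path_lengths is not None:
        pl = np.asarray(path_lengths, dtype=float)
        if len(pl) != len(pts):
            raise ValueError("path_lengths length mismatch")
        out["path_length"] = pl
        finite = np.isfinite(nn)
        if finite.sum() >= 2:
            out.attrs["pearson_r"] = float(pearsonr(pl[finite], nn[finite])[0])
            out.attrs["spearman_r"] = float(spearmanr(pl[finite], nn[finite])[0])
    return out


# ---------------------------------------------------------------------------
# tree morphometrics
# ---------------------------------------------------------------------------


def sholl_analysis(tree: TracedTree, center, radii: Sequence[float]) -> np.ndarray:
    """Sholl intersection profile: segment crossings per concentric sphere.

    For each radius the count of transversal crossings of tree segments with
    the sphere of that radius about ``center``; a segment's crossing
    parameters are the roots of a quadratic in its line parameter, counted in
    the half-open interval (0, 1] so a node sitting exactly on a sphere is
    attributed to its incoming segment only.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("radii must be non-empty")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing and positive")
    c = np.asarray(center, dtype=float)
    counts = np.zeros(len(radii), dtype=int)
    for p0, p1 in tree.edges():
        d = p1 - p0
        f = p0 - c
        a = float(d @ d)
        if a == 0:
            continue
        b = 2.0 * float(f @ d)
        c0 = float(f @ f)
        for k, r in enumerate(radii):
            disc = b * b - 4 * a * (c0 - r * r)
            if disc <= 0:
                continue  # miss or tangency: no transversal crossing
            sq = math.sqrt(disc)
            for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if 0.0 < t <= 1.0:
                    counts[k] += 1
    return counts


def horton_strahler(tree: TracedTree) -> int:
    """Strahler order of the root (leaves have order 1)."""
    children = tree.children()
    order: dict[int, int] = {}
    # post-order without recursion
    stack = [(tree.root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            ch = children[node]
            if not ch:
                order[node] = 1
            else:
                sub = [order[c] for c in ch]
                m = max(sub)
                order[node] = m + 1 if sub.count(m) >= 2 else m
        else:
            stack.append((node, True))
            for ch_node in children[node]:
                stack.append((ch_node, False))
    return order[tree.root]


# ---------------------------------------------------------------------------
# SWC I/O  (id, type, x, y, z, radius, parent; coordinates in µm)
# ---------------------------------------------------------------------------


def _parse_swc(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append(
                (int(parts[0]), float(parts[2]), float(parts[3]), float(parts[4]), int(parts[6]))
            )
    if not rows:
        raise ValueError(f"SWC file {path} contains no nodes")
    return pd.DataFrame(rows, columns=["id", "x", "y", "z", "parent"])


def read_swc_tree(path) -> TracedTree:
    """Read an SWC file as a rooted tree (parent −1 marks the root)."""
    df = _parse_swc(path)
    nodes = {int(r.id): np.array([r.z, r.y, r.x]) for r in df.itertuples()}
    parents = {int(r.id): (None if r.parent < 0 else int(r.parent)) for r in df.itertuples()}
    return TracedTree(nodes, parents)


def read_swc_path(path, id: str = "") -> TracedPath:
    """Read an unbranched SWC trace as an ordered polyline (root first)."""
    tree = read_swc_tree(path)
    children = tree.children()
    pts = [tree.nodes[tree.root]]
    cur = tree.root
    while children[cur]:
        if len(children[cur]) > 1:
            raise ValueError("SWC trace branches; use read_swc_tree")
        cur = children[cur][0]
        pts.append(tree.nodes[cur])
    return TracedPath(np.array(pts), id=id or str(path))


def write_swc(path, obj: TracedPath | TracedTree) -> None:
    """Write a path or tree in the standard 7-column SWC dialect."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        if isinstance(obj, TracedPath):
            for i, (z, y, x) in enumerate(obj.points, start=1):
                parent = i - 1 if i > 1 else -1
                fh.write(f"{i} 0 {x:.6f} {y:.6f} {z:.6f} 1.0 {parent}\n")
        else:
            for nid in sorted(obj.nodes):
                z, y, x = obj.nodes[nid]
                parent = obj.parents[nid]
                fh.write(f"{nid} 0 {x:.6f} {y:.6f} {z:.6f} 1.0 {-1 if parent is None else parent}\n")
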