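"""Skeleton-based centerline extraction.

Pipeline: topological thinning of the vessel mask, a 26-adjacency graph
over skeleton voxels with anisotropy-aware mm edge weights, Dijkstra
shortest path between two annotated endpoints, then cubic smoothing-spline
fitting against cumulative chordal arc length and uniform arc-length
resampling.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline
from skimage.morphology import skeletonize as _sk_skeletonize

from .image import BinaryMask

__all__ = [
    "Skeleton",
    "SkeletonGraph",
    "CenterlinePath",
    "PolylineMM",
    "PathQC",
    "NoPathError",
    "skeletonize_mask",
    "build_graph",
    "snap_endpoint",
    "shortest_path",
    "resample_polyline",
    "smooth_resample",
    "path_qc",
]

_OFFSETS_26 = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
)


class NoPathError(RuntimeError):
    """The two endpoints lie in different skeleton components."""


@dataclass
class Skeleton:
    """One-voxel-thick medial voxel set of a mask, with its grid geometry."""

    voxels: np.ndarray  # (N, 3) int, lexicographically sorted
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.voxels)

    def points_mm(self) -> np.ndarray:
        return np.asarray(self.origin) + self.voxels * np.asarray(self.spacing)


def skeletonize_mask(mask: BinaryMask) -> Skeleton:
    """3D topological thinning of the mask.

    Homotopy guard: thinning of near-symmetric even-width objects can erase
    a whole component; any mask component left without a skeleton voxel is
    re-seeded with its innermost voxel so the component count is preserved.
    """
    if not mask.values.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = np.asarray(_sk_skeletonize(mask.values), dtype=bool)
    structure = ndimage.generate_binary_structure(3, 3)
    labels, n_comp = ndimage.label(mask.values, structure=structure)
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        if not skel[comp_mask].any():
            edt = ndimage.distance_transform_edt(comp_mask, sampling=mask.spacing)
            skel[np.unravel_index(np.argmax(edt), edt.shape)] = True
    voxels = np.argwhere(skel)
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    return Skeleton(
        voxels=voxels[order],
        spacing=mask.spacing,
        origin=mask.origin,
        shape=mask.shape,
    )


@dataclass
class SkeletonGraph:
    """Undirected weighted graph over skeleton voxels (26-adjacency)."""

    voxels: np.ndarray  # (N, 3) int, lexicographically sorted (node id = row)
    adjacency: list[list[tuple[int, float]]]  # per node: (neighbor id, weight mm)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __len__(self) -> int:
        return len(self.voxels)

    def node_of(self, voxel) -> int:
        key = tuple(int(v) for v in voxel)
        try:
            return self._index[key]
        except AttributeError:
            self._index = {tuple(v): i for i, v in enumerate(self.voxels)}
            if key not in self._index:
                raise KeyError(f"voxel {key} is not a skeleton node")
            return self._index[key]
        except KeyError:
            raise KeyError(f"voxel {key} is not a skeleton node") from None


def build_graph(skeleton: Skeleton, spacing=None) -> SkeletonGraph:
    """Edges between 26-adjacent skeleton voxels, weighted by mm distance."""
    if len(skeleton) == 0:
        raise ValueError("cannot build a graph from an empty skeleton")
    sp = np.asarray(spacing if spacing is not None else skeleton.spacing, dtype=float)
    voxels = skeleton.voxels
    index = {tuple(v): i for i, v in enumerate(voxels)}
    adjacency: list[list[tuple[int, float]]] = [[] for _ in range(len(voxels))]
    offset_w = np.linalg.norm(_OFFSETS_26 * sp, axis=1)
    for i, v in enumerate(voxels):
        for off, w in zip(_OFFSETS_26, offset_w):
            j = index.get((int(v[0] + off[0]), int(v[1] + off[1]), int(v[2] + off[2])))
            if j is not None and j > i:
                adjacency[i].append((j, float(w)))
                adjacency[j].append((i, float(w)))
    return SkeletonGraph(
        voxels=voxels,
        adjacency=adjacency,
        spacing=tuple(float(s) for s in sp),
        origin=skeleton.origin,
    )


def snap_endpoint(point, skeleton: Skeleton, is_voxel: bool | None = None) -> tuple[np.ndarray, float]:
    """Nearest skeleton voxel (mm metric) to an annotated point.

    ``point`` may be a voxel index triple (integers) or an mm coordinate;
    set ``is_voxel`` to disambiguate, otherwise integer-valued input is
    treated as a voxel index.  Ties break to the lexicographically smallest
    voxel index.
    """
    if len(skeleton) == 0:
        raise ValueError("cannot snap to an empty skeleton")
    p = np.asarray(point, dtype=float)
    if is_voxel is None:
        is_voxel = np.issubdtype(np.asarray(point).dtype, np.integer)
    if is_voxel:
        p = np.asarray(skeleton.origin) + p * np.asarray(skeleton.spacing)
    d = np.linalg.norm(skeleton.points_mm() - p, axis=1)
    best = int(np.argmin(d))  # first minimum = lexicographically smallest (sorted voxels)
    return skeleton.voxels[best].copy(), float(d[best])


@dataclass
class CenterlinePath:
    """Ordered node walk from endpoint A to endpoint B on the skeleton graph."""

    nodes: list[int]
    voxels: np.ndarray  # (M, 3) int
    total_weight_mm: float
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def points_mm(self) -> np.ndarray:
        return np.asarray(self.origin) + self.voxels * np.asarray(self.spacing)


def shortest_path(graph: SkeletonGraph, a, b) -> CenterlinePath:
    """Dijkstra between nodes ``a`` and ``b`` (node ids or voxel triples).

    Deterministic: among equal-weight paths the lexicographically smaller
    predecessor is preferred.  Raises :class:`NoPathError` when the
    endpoints are in different components, ``KeyError``/``ValueError`` for
    invalid nodes.
    """
    a = a if np.isscalar(a) else graph.node_of(a)
    b = b if np.isscalar(b) else graph.node_of(b)
    n = len(graph)
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError(f"node ids must be in [0, {n}), got {a}, {b}")
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=int)
    done = np.zeros(n, dtype=bool)
    dist[a] = 0.0
    heap: list[tuple[float, int]] = [(0.0, a)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == b:
            break
        for v, w in graph.adjacency[u]:
            nd = d + w
            if nd < dist[v] - 1e-12:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= 1e-12 and pred[v] != -1 and u < pred[v]:
                pred[v] = u
    if not np.isfinite(dist[b]):
        raise NoPathError(f"no path between nodes {a} and {b}: endpoints in different components")
    nodes = [int(b)]
    while nodes[-1] != a:
        nodes.append(int(pred[nodes[-1]]))
    nodes.reverse()
    return CenterlinePath(
        nodes=nodes,
        voxels=graph.voxels[nodes],
        total_weight_mm=float(dist[b]),
        spacing=graph.spacing,
        origin=graph.origin,
    )


@dataclass
class PolylineMM:
    """Smoothed centerline: ordered mm points at a uniform arc-length step."""

    points: np.ndarray  # (N, 3)
    step: float  # nominal arc-length step, mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise ValueError(f"a polyline needs >= 3 points, got {len(self.points)}")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.points, dtype=dtype)

    def __len__(self) -> int:
        return len(self.points)


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points, step: float) -> np.ndarray:
    """Uniformly resample a polyline at (close to) ``step`` mm arc length.

    The actual step is ``L / round(L / step)`` so the last point is kept.
    """
    points = np.asarray(points, dtype=float)
    s = _cumulative_arclength(points)
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length polyline")
    n_out = max(3, int(round(total / step)) + 1)
    si = np.linspace(0.0, total, n_out)
    return np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])


def smooth_resample(
    path: CenterlinePath,
    spacing=None,
    step: float = 0.5,
    smoothing: float = 0.1,
) -> PolylineMM:
    """Cubic smoothing spline per coordinate against chordal arc length,
    then uniform arc-length resampling.

    ``smoothing`` is the per-point mean squared residual budget (mm^2) of
    the spline fit, so the total spline smoothing factor grows with point
    count; 0 interpolates exactly.
    """
    voxels = getattr(path, "voxels", None)
    if voxels is not None:
        sp = np.asarray(spacing if spacing is not None else path.spacing, dtype=float)
        pts = np.asarray(path.origin) + voxels * sp
    else:
        pts = np.asarray(path, dtype=float)
    if len(pts) < 4:
        raise ValueError(f"smooth_resample requires >= 4 path nodes, got {len(pts)}")
    u = _cumulative_arclength(pts)
    s_factor = smoothing * len(pts)
    dense_n = max(10 * len(pts), 1000)
    ud = np.linspace(0.0, u[-1], dense_n)
    dense = np.column_stack(
        [UnivariateSpline(u, pts[:, k], k=3, s=s_factor)(ud) for k in range(3)]
    )
    return PolylineMM(points=resample_polyline(dense, step), step=step)


@dataclass(frozen=True)
class PathQC:
    """Numeric stand-in for visual path inspection."""

    chord_path_ratio: float  # Euclidean endpoint distance / path length, in (0, 1]
    snap_distances_mm: tuple[float, ...]
    accepted: bool
    reasons: tuple[str, ...] = ()


def path_qc(
    path: CenterlinePath,
    snap_distances_mm=(),
    max_snap_mm: float = 5.0,
    max_chord_ratio: float = 1.0,
) -> PathQC:
    """Flag a path suspect when an endpoint snapped too far or when the
    chord/path ratio exceeds ``max_chord_ratio`` (implausibly straight,
    i.e. a shortcut through a loop).  Defaults accept straight paths."""
    pts = path.points_mm()
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    length = max(path.total_weight_mm, 1e-12)
    ratio = min(chord / length, 1.0) if length > 0 else 1.0
    if len(path.nodes) == 1:
        ratio = 1.0
    reasons = []
    if any(d > max_snap_mm for d in snap_distances_mm):
        worst = max(snap_distances_mm)
        reasons.append(f"endpoint snap distance {worst:.2f} mm exceeds {max_snap_mm:.2f} mm")
    if ratio > max_chord_ratio:
        reasons.append(f"chord/path ratio {ratio:.4f} exceeds {max_chord_ratio:.4f}")
    return PathQC(
        chord_path_ratio=ratio,
        snap_distances_mm=tuple(float(d) for d in snap_distances_mm),
        accepted=not reasons,
        reasons=tuple(reasons),
    )
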