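"""Lumen geometry: false-lumen derivation, centerline, analysis planes.

The false lumen is obtained by subtracting the true-lumen segmentation
from the whole-aorta segmentation. A 3D centerline is extracted from the
true-lumen mask by skeletonization, graph-diameter path search, smoothing
and arc-length spline resampling at 1 mm, giving orthogonal analysis
planes (point + unit tangent) every millimeter. Every luminal voxel — in
both lumens — is then matched to the nearest plane; the plane tangent
defines the local forward-flow direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize


class ContainmentError(ValueError):
    """True-lumen voxels fall outside the whole-aorta segmentation."""


class GeometryError(ValueError):
    """Mask too small or degenerate for centerline extraction."""


@dataclass
class LumenSegmentation:
    """Aligned binary masks for whole aorta, TL and FL on one grid."""

    aorta_mask: np.ndarray
    tl_mask: np.ndarray
    fl_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.aorta_mask.shape == self.tl_mask.shape == self.fl_mask.shape):
            raise ValueError("masks must share one grid")
        if not self.tl_mask.any():
            raise ValueError("true-lumen mask is empty")

    @property
    def lumen_mask(self) -> np.ndarray:
        return self.tl_mask | self.fl_mask


@dataclass
class CenterlinePlanes:
    """Ordered centerline points with unit tangents (plane normals)."""

    points_mm: np.ndarray  # (n, 3) physical (x, y, z)
    tangents: np.ndarray  # (n, 3) unit vectors
    arc_length_mm: np.ndarray  # (n,)

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass
class VoxelPlaneAssignment:
    """Nearest-plane index per luminal voxel (-1 outside the lumens)."""

    plane_index: np.ndarray  # int array [z, y, x]

    def indices_for(self, mask: np.ndarray) -> np.ndarray:
        return self.plane_index[mask]


def derive_false_lumen(
    aorta_mask: np.ndarray, tl_mask: np.ndarray, voxel_size_mm
) -> LumenSegmentation:
    """FL = aorta AND NOT TL (exact voxelwise subtraction)."""
    aorta_mask = np.asarray(aorta_mask, dtype=bool)
    tl_mask = np.asarray(tl_mask, dtype=bool)
    outside = tl_mask & ~aorta_mask
    if outside.any():
        raise ContainmentError(
            f"{int(outside.sum())} true-lumen voxels lie outside the aorta segmentation"
        )
    fl_mask = aorta_mask & ~tl_mask
    if not fl_mask.any():
        warnings.warn("false lumen is empty (non-dissected aorta)", stacklevel=2)
    return LumenSegmentation(
        aorta_mask=aorta_mask,
        tl_mask=tl_mask,
        fl_mask=fl_mask,
        voxel_size_mm=tuple(voxel_size_mm),
    )


def _voxel_centers_mm(idx_zyx: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Physical (x, y, z) coordinates of [z, y, x] index rows."""
    sx, sy, sz = voxel_size_mm
    return np.stack(
        [idx_zyx[:, 2] * sx, idx_zyx[:, 1] * sy, idx_zyx[:, 0] * sz], axis=1
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n <= 1:
        return mask
    warnings.warn(
        f"true-lumen mask has {n} connected components; using the largest", stacklevel=3
    )
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _ridge_path_mm(mask: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Centerline as a distance-transform-ridge geodesic through the mask.

    Fallback when thinning degenerates (an exactly even-symmetric tube has
    no unique central voxel layer and 3D thinning can erase it entirely).
    Edges between 26-neighboring mask voxels are weighted by physical step
    length divided by the local wall distance, so the cheapest path hugs
    the medial ridge; endpoints come from a double Dijkstra sweep.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    nz, ny, nx = mask.shape
    step = np.array([voxel_size_mm[2], voxel_size_mm[1], voxel_size_mm[0]])
    dt = ndimage.distance_transform_edt(mask, sampling=step)
    flat = np.arange(mask.size).reshape(mask.shape)
    node_of = -np.ones(mask.size, dtype=np.int64)
    voxels = np.argwhere(mask)
    node_of[flat[mask]] = np.arange(len(voxels))

    rows, cols, weights = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    for off in offsets:
        sl_a, sl_b = [], []
        for d, n in zip(off, (nz, ny, nx)):
            sl_a.append(slice(max(d, 0), n + min(d, 0)))
            sl_b.append(slice(max(-d, 0), n + min(-d, 0)))
        both = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        ia = flat[tuple(sl_a)][both]
        ib = flat[tuple(sl_b)][both]
        length = float(np.linalg.norm(np.asarray(off) * step))
        w = length / (0.5 * (dt.ravel()[ia] + dt.ravel()[ib]) + 0.25)
        rows.append(node_of[ia])
        cols.append(node_of[ib])
        weights.append(w)
    n_nodes = len(voxels)
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_nodes, n_nodes),
    ).tocsr()

    start = int(node_of[flat[mask]][np.argmax(dt[mask])])
    d0 = dijkstra(graph, directed=False, indices=start)
    u = int(np.argmax(np.where(np.isfinite(d0), d0, -np.inf)))
    d1, pred = dijkstra(graph, directed=False, indices=u, return_predecessors=True)
    v = int(np.argmax(np.where(np.isfinite(d1), d1, -np.inf)))
    path = [v]
    while path[-1] != u and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    order = np.array(path[::-1])
    # the sweep endpoints sit on the wall; trim the off-ridge tails so the
    # retained path stays near the medial axis (extension restores length)
    dt_path = dt[tuple(voxels[order].T)]
    good = np.flatnonzero(dt_path >= 0.85 * dt_path.max())
    if len(good) >= 12:
        order = order[good[0] : good[-1] + 1][3:-3]
    return _voxel_centers_mm(voxels[order], voxel_size_mm)


def _skeleton_path_mm(tl_mask: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Longest geodesic path through the skeleton, in physical mm."""
    skel = skeletonize(tl_mask)
    coords = np.argwhere(skel)
    if len(coords) < max(5, 0.02 * tl_mask.sum() ** (1 / 3)):
        # thinning collapsed (e.g. even-symmetric tube); use the ridge path
        if tl_mask.sum() < 8:
            raise GeometryError("true-lumen mask too small for a centerline")
        return _ridge_path_mm(tl_mask, voxel_size_mm)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = np.array(
        [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    )
    step = np.array([voxel_size_mm[2], voxel_size_mm[1], voxel_size_mm[0]])
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                g.add_edge(i, j, weight=float(np.linalg.norm(off * step)))
    # double-sweep: farthest node from an arbitrary start, then farthest from it
    comp = max(nx.connected_components(g), key=len)
    start = next(iter(comp))
    d0 = nx.single_source_dijkstra_path_length(g, start)
    u = max(d0, key=d0.get)
    d1, paths = nx.single_source_dijkstra(g, u)
    v = max(d1, key=d1.get)
    path_idx = np.array(paths[v])
    return _voxel_centers_mm(coords[path_idx], voxel_size_mm)


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    if len(points) <= window:
        return points
    pad = window // 2
    padded = np.pad(points, ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    return np.stack(
        [np.convolve(padded[:, i], kernel, mode="valid") for i in range(3)], axis=1
    )


def _fit_axis_splines(s: np.ndarray, points: np.ndarray):
    """Per-coordinate smoothing splines over arc-length parameter.

    Residual voxel-level jitter in the path translates into lateral plane
    wobble that distorts nearest-plane voxel assignment far from the axis,
    so a smoothing spline (~0.3 mm rms tolerance) is fitted instead of an
    exact interpolant; falls back to exact cubic splines for short paths.
    """
    from scipy.interpolate import make_smoothing_spline

    if len(points) < 10:
        return [CubicSpline(s, points[:, i]) for i in range(3)]
    try:
        lam = float(len(points))  # generous roughness penalty; ~sub-voxel fit
        return [make_smoothing_spline(s, points[:, i], lam=lam) for i in range(3)]
    except Exception:
        return [CubicSpline(s, points[:, i]) for i in range(3)]


def _extend_to_mask_ends(
    points: np.ndarray, mask: np.ndarray, voxel_size_mm, step_mm: float = 0.5
) -> np.ndarray:
    """Extend both ends along the end tangents while still inside the mask.

    Skeletonization retreats from the vessel ends by roughly one radius;
    linear extension restores coverage of the full luminal length.
    """
    sx, sy, sz = voxel_size_mm
    shape = mask.shape

    def inside(p):
        iz = int(round(p[2] / sz))
        iy = int(round(p[1] / sy))
        ix = int(round(p[0] / sx))
        return (
            0 <= iz < shape[0]
            and 0 <= iy < shape[1]
            and 0 <= ix < shape[2]
            and mask[iz, iy, ix]
        )

    def walk(p0, direction):
        extra = []
        p = p0.copy()
        for _ in range(1000):
            p = p + direction * step_mm
            if not inside(p):
                break
            extra.append(p.copy())
        return extra

    def end_direction(segment: np.ndarray, outward: np.ndarray) -> np.ndarray | None:
        # principal direction of the end segment; robust to 1-voxel wiggles
        seg = segment - segment.mean(axis=0)
        if len(segment) < 2 or not np.any(seg):
            return None
        _, _, vt = np.linalg.svd(seg, full_matrices=False)
        d = vt[0]
        if float(d @ outward) < 0:
            d = -d
        return d

    k = min(15, len(points))
    t_start = end_direction(points[:k], points[0] - points[k - 1])
    t_end = end_direction(points[-k:], points[-1] - points[-k])
    head = walk(points[0], t_start)[::-1] if t_start is not None else []
    tail = walk(points[-1], t_end) if t_end is not None else []
    return np.vstack([*head, points, *tail]) if (head or tail) else points


def extract_centerline(
    tl_mask: np.ndarray,
    voxel_size_mm,
    velocity: np.ndarray | None = None,
    spacing_mm: float = 1.0,
    smooth_window: int = 5,
) -> CenterlinePlanes:
    """Centerline of the true lumen with planes every ``spacing_mm``.

    Pipeline: 3D skeletonization -> graph of skeleton voxels (26-connected,
    physical edge lengths) -> longest shortest path (graph diameter) ->
    moving-average smoothing -> linear extension to the mask ends ->
    cubic-spline resampling at uniform arc length. Tangents are the
    normalized spline derivative. If ``velocity`` ([phase, z, y, x, 3]) is
    given, the point order is flipped so that arc length increases along
    the net luminal flow direction.
    """
    tl_mask = _largest_component(np.asarray(tl_mask, dtype=bool))
    raw = _skeleton_path_mm(tl_mask, voxel_size_mm)
    smooth = _moving_average(raw, smooth_window)
    smooth = _extend_to_mask_ends(smooth, tl_mask, voxel_size_mm)
    smooth = _moving_average(smooth, smooth_window)

    seg = np.linalg.norm(np.diff(smooth, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    smooth = smooth[keep]
    if len(smooth) < 4:
        raise GeometryError("centerline path too short for spline resampling")
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(smooth, axis=0), axis=1))])
    splines = _fit_axis_splines(s, smooth)

    dense_s = np.arange(0.0, s[-1] + 1e-9, 0.05)
    dense = np.stack([sp(dense_s) for sp in splines], axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    targets = np.arange(0.0, arc[-1] + 1e-9, spacing_mm)
    params = np.interp(targets, arc, dense_s)
    points = np.stack([sp(params) for sp in splines], axis=1)
    tangents = np.stack([sp(params, 1) for sp in splines], axis=1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    if velocity is not None:
        chord = points[-1] - points[0]
        vmean = velocity[:, tl_mask, :].mean(axis=(0, 1))
        if float(vmean @ chord) < 0:
            points = points[::-1].copy()
            tangents = -tangents[::-1].copy()
            targets = targets[-1] - targets[::-1]

    return CenterlinePlanes(points_mm=points, tangents=tangents, arc_length_mm=targets)


def assign_voxels_to_planes(
    seg: LumenSegmentation, cl: CenterlinePlanes
) -> VoxelPlaneAssignment:
    """Match every luminal voxel (TL and FL) to its nearest plane point."""
    if len(cl) == 0:
        raise GeometryError("empty centerline")
    lumen = seg.lumen_mask
    idx_zyx = np.argwhere(lumen)
    centers = _voxel_centers_mm(idx_zyx, seg.voxel_size_mm)
    tree = cKDTree(cl.points_mm)
    _, nearest = tree.query(centers, k=1)
    plane_index = np.full(lumen.shape, -1, dtype=np.int32)
    plane_index[lumen] = nearest
    return VoxelPlaneAssignment(plane_index=plane_index)
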