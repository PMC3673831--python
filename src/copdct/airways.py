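"""Bronchial morphometry: lumen segmentation, centerline, ray-cast wall
measurement and the Pi10 summary.

Pipeline (each stage usable on its own):

1. :func:`segment_lumen` — threshold region growing from a seed inside an
   air-filled lumen, with a geometrically increasing threshold schedule and a
   volume-explosion (leak) criterion.
2. :func:`extract_centerline` — centerline model of the lumen mask via
   minimum-cost paths along the ridge of the Euclidean distance transform
   (iterative furthest-tip tracing), spur suppression, rooting at the seed
   and generation labelling (0 = trachea segment, 1 = after the first
   bifurcation, ...).
3. :func:`sample_cross_sections` — cross-section sites perpendicular to the
   local airway direction at fixed arc spacing (default 1 mm).
4. :func:`measure_wall` — 72 radial rays per cross-section, HU sampled by
   trilinear interpolation at sub-voxel steps; inner wall boundary at the
   half-rise between lumen plateau and wall peak, outer boundary at the
   half-fall toward the parenchyma plateau (a full-width-at-half-maximum
   style detector).  Lumen perimeter Pi and wall area WA come from the
   polygons through the per-ray boundary points; rays without a detectable
   wall are interpolated angularly when few, or fail the section when >25%.
5. :func:`filter_cross_sections` — excludes trachea/main-bronchus sections,
   sections near bifurcations, and failed sections, with a per-reason tally.
6. :func:`compute_pi10` — ordinary least squares of sqrt(WA) on Pi across the
   surviving sections; Pi10 = predicted sqrt(WA) at a 10 mm lumen perimeter,
   the subject-level bronchial wall-thickness index.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse, stats
from scipy.sparse.csgraph import dijkstra

from .errors import (
    DegenerateInputError,
    DegenerateMaskError,
    DegenerateRegressionError,
    GeometryError,
    SeedPointError,
)
from .volume import CTVolume

N_RAYS_DEFAULT = 72


# ---------------------------------------------------------------------------
# 1. lumen segmentation
# ---------------------------------------------------------------------------

@dataclass
class LumenSegmentation:
    mask: np.ndarray
    threshold_hu: float
    failed: bool = False  # leak at the minimum threshold


def segment_lumen(
    vol: CTVolume,
    seed_point_mm,
    t_start: float = -980.0,
    step_init: float = 5.0,
    t_max: float = -500.0,
    leak_factor: float = 2.0,
) -> LumenSegmentation:
    """Grow the airway lumen from a seed with an adaptive threshold.

    The threshold starts at ``t_start`` and is raised by a step that doubles
    each round (5, 10, 20, ... HU).  After each raise, the 6-connected
    component of ``HU < t`` containing the seed is taken; if its volume more
    than ``leak_factor``-folds relative to the previous accepted component,
    the growth is deemed a leak into the parenchyma and the previous
    threshold is kept.  A leak at the very first threshold sets ``failed``
    instead of raising.
    """
    seed_idx = np.round(vol.world_to_index(seed_point_mm)).astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= np.asarray(vol.shape)):
        raise GeometryError("seed point outside the volume")
    seed_hu = float(vol.voxels[tuple(seed_idx)])
    if seed_hu >= -900.0:
        raise SeedPointError(
            f"seed voxel HU = {seed_hu:.0f}; expected air-filled lumen (< -900 HU)"
        )

    def component(threshold):
        binary = vol.voxels < threshold
        labels, _ = ndimage.label(binary)  # default structure = 6-connectivity
        lab = labels[tuple(seed_idx)]
        if lab == 0:
            return None
        return labels == lab

    prev_mask = component(t_start)
    if prev_mask is None:
        raise SeedPointError("seed voxel not below the starting threshold")
    prev_size = int(prev_mask.sum())
    prev_t = t_start

    step = step_init
    t = t_start + step
    first = True
    while t <= t_max:
        mask = component(t)
        size = int(mask.sum())
        if size > leak_factor * prev_size:
            if first:
                return LumenSegmentation(prev_mask, prev_t, failed=True)
            return LumenSegmentation(prev_mask, prev_t, failed=False)
        prev_mask, prev_size, prev_t = mask, size, t
        step *= 2.0
        t = prev_t + step
        first = False
    return LumenSegmentation(prev_mask, prev_t, failed=False)


# ---------------------------------------------------------------------------
# 2. centerline tree
# ---------------------------------------------------------------------------

@dataclass
class Branch:
    """A maximal non-branching chain of centerline nodes."""

    points_mm: np.ndarray  # (n, 3) ordered from the root side outward
    generation_label: int

    @property
    def arc_length_mm(self) -> float:
        if len(self.points_mm) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1).sum())


@dataclass
class AirwayTree:
    """Rooted centerline model: branches plus bifurcation points."""

    branches: list[Branch]
    bifurcations_mm: np.ndarray  # (k, 3) world coords of branching nodes
    root_mm: np.ndarray

    @property
    def n_bifurcations(self) -> int:
        return len(self.bifurcations_mm)

    @property
    def total_arc_length_mm(self) -> float:
        return float(sum(b.arc_length_mm for b in self.branches))


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)  # half of the 26-neighborhood (undirected)
]


def _mask_graphs(mask: np.ndarray, spacing, D: np.ndarray):
    """Sparse 26-connectivity graphs over mask voxels.

    Returns (ids, length_graph, cost_graph): edge length in mm, and a
    medialness cost = length / (eps + mean-depth^2) that makes minimum-cost
    paths hug the ridge of the distance transform (the airway axis).
    """
    idx = np.argwhere(mask)
    n = len(idx)
    ids = np.full(mask.shape, -1, np.int64)
    ids[tuple(idx.T)] = np.arange(n)
    Dm = D

    rows, cols, lens, costs = [], [], [], []
    eps = 0.25  # mm^2; keeps the cost finite in 1-voxel-deep regions
    for off in _NEIGHBOR_OFFSETS:
        sl_a, sl_b = [], []
        for k, o in enumerate(off):
            if o >= 0:
                sl_a.append(slice(0, mask.shape[k] - o))
                sl_b.append(slice(o, mask.shape[k]))
            else:
                sl_a.append(slice(-o, mask.shape[k]))
                sl_b.append(slice(0, mask.shape[k] + o))
        A = ids[tuple(sl_a)].ravel()
        B = ids[tuple(sl_b)].ravel()
        ok = (A >= 0) & (B >= 0)
        a, b = A[ok], B[ok]
        if a.size == 0:
            continue
        length = float(np.linalg.norm(np.asarray(off) * np.asarray(spacing)))
        da = Dm[tuple(idx[a].T)]
        db = Dm[tuple(idx[b].T)]
        cost = length / (eps + (0.5 * (da + db)) ** 2)
        rows.extend([a, b])
        cols.extend([b, a])
        lens.extend([np.full(a.size, length)] * 2)
        costs.extend([cost, cost])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    g_len = sparse.csr_matrix(
        (np.concatenate(lens), (rows, cols)), shape=(n, n)
    )
    g_cost = sparse.csr_matrix(
        (np.concatenate(costs), (rows, cols)), shape=(n, n)
    )
    return ids, g_len, g_cost


def _backtrack(pred: np.ndarray, tip: int) -> list[int]:
    """Follow predecessors from tip to the source; returns source..tip order."""
    path = [tip]
    cur = tip
    while pred[cur] >= 0:
        cur = int(pred[cur])
        path.append(cur)
    path.reverse()
    return path


def extract_centerline(
    mask: np.ndarray,
    spacing,
    seed_point_mm=None,
    prune_mm: float = 3.0,
    max_branches: int = 100,
) -> AirwayTree:
    """Centerline model of a lumen mask via distance-ridge minimum-cost paths.

    The Euclidean distance transform D of the mask is computed in world
    units; paths through the voxel graph are penalized by 1/D^2 so minimum-
    cost routes follow the medial axis.  The main path runs from the root
    (mask voxel nearest ``seed_point_mm``, or the deepest voxel) to the
    geodesically furthest voxel; further branches are added iteratively from
    the furthest remaining voxel back to the existing centerline, until the
    candidate's geodesic reach no longer exceeds ``prune_mm`` plus the local
    airway radius at its attachment (which suppresses corner spurs at open
    tube ends).  Branches are split at attachment points; generation labels
    count bifurcations from the root (0 = trachea segment).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise DegenerateInputError("empty lumen mask")
    spacing = np.asarray(spacing, float)
    D = ndimage.distance_transform_edt(mask, sampling=spacing)
    if D.max() <= min(spacing):
        raise DegenerateMaskError("mask has no interior (single-voxel thin)")

    idx = np.argwhere(mask)
    pos = idx * spacing
    ids, g_len, g_cost = _mask_graphs(mask, spacing, D)
    D_flat = D[tuple(idx.T)]

    if seed_point_mm is not None:
        root = int(np.argmin(np.linalg.norm(pos - np.asarray(seed_point_mm), axis=1)))
    else:
        root = int(np.argmax(D_flat))

    dist_len = dijkstra(g_len, indices=root, min_only=False)
    finite = np.isfinite(dist_len)
    tip = int(np.argmax(np.where(finite, dist_len, -np.inf)))
    _, pred = dijkstra(g_cost, indices=root, min_only=False, return_predecessors=True)
    main_path = _backtrack(pred, tip)

    raw_paths: list[list[int]] = [main_path]
    attach_nodes: list[int | None] = [None]
    on_centerline = np.zeros(len(idx), bool)
    on_centerline[main_path] = True

    for _ in range(max_branches):
        sources = np.flatnonzero(on_centerline)
        dl = dijkstra(g_len, indices=sources, min_only=True)
        dl = np.where(np.isfinite(dl), dl, -np.inf)
        tip = int(np.argmax(dl))
        dc, pred_c, src_c = dijkstra(
            g_cost, indices=sources, min_only=True, return_predecessors=True
        )
        attach = int(src_c[tip]) if src_c[tip] >= 0 else -1
        if attach < 0 or dl[tip] <= prune_mm + float(D_flat[attach]):
            break
        path = _backtrack(pred_c, tip)  # attach .. tip
        raw_paths.append(path)
        attach_nodes.append(path[0])
        on_centerline[path] = True

    return _assemble_tree(raw_paths, attach_nodes, pos, spacing, mask, D)


def _smooth_polyline(pts: np.ndarray, window_mm: float = 5.0) -> np.ndarray:
    """Moving-average smoothing of a voxel-stepped path to a sub-voxel curve."""
    if len(pts) < 5:
        return pts
    step = float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    w = max(3, int(round(window_mm / max(step, 1e-6))) | 1)
    w = min(w, len(pts) if len(pts) % 2 else len(pts) - 1)
    return ndimage.uniform_filter1d(pts, size=w, axis=0, mode="nearest")


def _recenter_polyline(pts: np.ndarray, mask: np.ndarray, spacing, D) -> np.ndarray:
    """Snap each path point to the lumen centroid in its normal plane.

    Minimum-cost voxel paths ride the distance-transform ridge but drift
    toward corners at open mask ends where the ridge is flat; recentering on
    the in-plane mask centroid removes that bias and yields a sub-voxel
    axis estimate.
    """
    if len(pts) < 2:
        return pts
    spacing = np.asarray(spacing, float)
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents = tangents / np.where(norms > 0, norms, 1.0)
    maskf = mask.astype(np.float32)
    out = pts.copy()
    step = float(min(spacing)) / 2.0
    for k, (pt, tg) in enumerate(zip(pts, tangents)):
        # local radius estimate from the EDT near this point
        ci = np.clip(np.round(pt / spacing).astype(int), 0, np.asarray(mask.shape) - 1)
        radius = max(float(D[tuple(ci)]) * 1.8, 2.0 * step)
        u, v = _plane_basis(tg)
        n_s = max(int(np.ceil(2 * radius / step)) + 1, 3)
        offs = np.linspace(-radius, radius, n_s)
        aa, bb = np.meshgrid(offs, offs, indexing="ij")
        disc = aa**2 + bb**2 <= radius**2
        a, b = aa[disc], bb[disc]
        sample_pts = pt[None] + a[:, None] * u[None] + b[:, None] * v[None]
        coords = (sample_pts / spacing).T
        inside = ndimage.map_coordinates(maskf, coords, order=1, mode="constant") >= 0.5
        if inside.sum() >= 3:
            out[k] = pt + float(a[inside].mean()) * u + float(b[inside].mean()) * v
    return out


def _straighten_end(pts: np.ndarray, radius_mm: float, at_start: bool) -> np.ndarray:
    """Replace the last ``radius_mm`` of a free branch end with a linear
    extrapolation of the adjacent interior direction.

    Near an open mask end the distance-transform ridge flattens and the
    traced path (and its recentered version) curls toward the boundary;
    the interior direction is the unbiased axis estimate there.
    """
    if len(pts) < 5:
        return pts
    p = pts[::-1] if at_start else pts
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s_from_end = arc[-1] - arc
    inner = (s_from_end >= radius_mm) & (s_from_end <= 3.0 * radius_mm)
    tail = s_from_end < radius_mm
    if inner.sum() < 2 or not tail.any():
        return pts
    ref = p[inner]
    direction = ref[-1] - ref[0]
    nd = np.linalg.norm(direction)
    if nd == 0:
        return pts
    direction /= nd
    anchor_idx = int(np.flatnonzero(inner)[-1])
    anchor_s = arc[anchor_idx]
    out = p.copy()
    out[tail] = p[anchor_idx] + (arc[tail] - anchor_s)[:, None] * direction
    return out[::-1] if at_start else out


def _assemble_tree(raw_paths, attach_nodes, pos, spacing, mask, D) -> AirwayTree:
    """Split raw tip-traced paths at attachment points; label generations."""
    # owner raw path and position of every attachment
    splits_per_path: dict[int, list[int]] = {i: [] for i in range(len(raw_paths))}
    child_attach: dict[int, tuple[int, int]] = {}  # child -> (parent, pos)
    for j, attach in enumerate(attach_nodes):
        if attach is None:
            continue
        found = False
        for i in range(j):
            if attach in raw_paths[i]:
                p = raw_paths[i].index(attach)
                splits_per_path[i].append(p)
                child_attach[j] = (i, p)
                found = True
                break
        if not found:  # attachment on a node added by a later path; rare
            child_attach[j] = (0, 0)
            splits_per_path[0].append(0)

    base_gen: dict[int, int] = {0: 0}
    branches: list[Branch] = []
    bif_nodes: set[int] = set()
    for i, path in enumerate(raw_paths):
        splits = sorted(set(splits_per_path[i]) - {0, len(path) - 1})
        interior_all = sorted(set(splits_per_path[i]))
        if i in child_attach:
            parent, p = child_attach[i]
            parent_splits = sorted(set(splits_per_path[parent]) - {0, len(raw_paths[parent]) - 1})
            k = sum(1 for s in parent_splits if s <= p)
            if p in parent_splits:
                # sibling of the parent's continuing segment after this split
                base_gen[i] = base_gen[parent] + k
            else:
                # attached at the parent's tip: one bifurcation deeper
                base_gen[i] = base_gen[parent] + k + 1
        bounds = [0] + splits + [len(path) - 1]
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            if hi - lo < 1:
                continue
            seg = np.asarray(path[lo : hi + 1])
            pts = _smooth_polyline(pos[seg])
            pts = _recenter_polyline(pts, mask, spacing, D)
            vox = np.clip(
                np.round(pts / spacing).astype(int), 0, np.asarray(mask.shape) - 1
            )
            radius = float(np.percentile(D[tuple(vox.T)], 90))
            if hi == len(path) - 1:  # free tip end
                pts = _straighten_end(pts, radius, at_start=False)
            if i == 0 and lo == 0:  # the root end of the trachea
                pts = _straighten_end(pts, radius, at_start=True)
            pts = _smooth_polyline(pts, window_mm=2.0)
            branches.append(Branch(points_mm=pts, generation_label=base_gen[i] + k))
        for s in interior_all:
            bif_nodes.add(path[s])

    bif_pts = (
        pos[sorted(bif_nodes)] if bif_nodes else np.empty((0, 3))
    )
    root_mm = pos[raw_paths[0][0]]
    return AirwayTree(branches=branches, bifurcations_mm=np.asarray(bif_pts), root_mm=root_mm)


# ---------------------------------------------------------------------------
# 3. cross-section sampling
# ---------------------------------------------------------------------------

@dataclass
class CrossSectionSite:
    center_mm: np.ndarray
    normal: np.ndarray  # unit local tangent
    generation_label: int
    bifurcation_distance_mm: float


def sample_cross_sections(
    tree: AirwayTree, spacing_mm: float = 1.0
) -> list[CrossSectionSite]:
    """Sites along each branch at fixed arc spacing, normal = local tangent.

    Tangents use central differences of the branch polyline (one-sided at the
    ends).  Branches shorter than the spacing yield no sections.
    """
    sites: list[CrossSectionSite] = []
    for branch in tree.branches:
        pts = branch.points_mm
        if len(pts) < 2:
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        if total < spacing_mm:
            continue
        tangents = np.gradient(pts, arc, axis=0)
        norms = np.linalg.norm(tangents, axis=1, keepdims=True)
        tangents = tangents / np.where(norms > 0, norms, 1.0)
        targets = np.arange(spacing_mm, total, spacing_mm)
        for s in targets:
            center = np.array(
                [np.interp(s, arc, pts[:, k]) for k in range(3)]
            )
            normal = np.array([np.interp(s, arc, tangents[:, k]) for k in range(3)])
            nn = np.linalg.norm(normal)
            if nn == 0:
                continue
            normal /= nn
            if tree.n_bifurcations:
                bd = float(
                    np.min(np.linalg.norm(tree.bifurcations_mm - center, axis=1))
                )
            else:
                bd = float("inf")
            sites.append(
                CrossSectionSite(
                    center_mm=center,
                    normal=normal,
                    generation_label=branch.generation_label,
                    bifurcation_distance_mm=bd,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# 4. ray-cast wall measurement
# ---------------------------------------------------------------------------

@dataclass
class WallCrossSection:
    """One perpendicular bronchial slice with per-ray wall boundaries."""

    center_mm: np.ndarray
    normal: np.ndarray
    inner_radii_mm: np.ndarray  # (n_rays,) NaN where the ray failed
    outer_radii_mm: np.ndarray
    lumen_perimeter_mm: float  # Pi
    wall_area_mm2: float  # WA
    status: str = "valid"  # "valid" | "excluded"
    exclusion_reason: str | None = None
    generation_label: int = 2
    bifurcation_distance_mm: float = float("inf")

    @property
    def sqrt_wall_area_mm(self) -> float:
        return float(np.sqrt(self.wall_area_mm2)) if self.wall_area_mm2 > 0 else float("nan")

    @property
    def n_missing_rays(self) -> int:
        return int(np.isnan(self.inner_radii_mm).sum())


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def measure_wall(
    vol: CTVolume,
    center_mm,
    normal,
    n_rays: int = N_RAYS_DEFAULT,
    step_mm: float = 0.1,
    max_radius_mm: float = 10.0,
    min_contrast_hu: float = 150.0,
    missing_ray_tolerance: float = 0.25,
    generation_label: int = 2,
    bifurcation_distance_mm: float = float("inf"),
) -> WallCrossSection:
    """Cast ``n_rays`` radial rays in the plane perpendicular to ``normal``.

    Boundary rule per ray (FWHM-style): the wall is the highest-attenuation
    peak along the ray; the inner boundary is where the profile first crosses
    halfway between the lumen plateau and the peak, the outer boundary where
    it falls halfway between the peak and the parenchyma plateau beyond.
    Rays whose peak rises less than ``min_contrast_hu`` above the lumen
    plateau, or that never fall off again, are marked missing; missing rays
    are angularly interpolated unless they exceed ``missing_ray_tolerance``,
    in which case the section's status is ``excluded``.
    """
    center = np.asarray(center_mm, float)
    if not vol.contains_world(center):
        raise GeometryError("cross-section center outside the volume")
    u, v = _plane_basis(normal)
    thetas = 2.0 * np.pi * np.arange(n_rays) / n_rays
    dirs = np.cos(thetas)[:, None] * u[None] + np.sin(thetas)[:, None] * v[None]
    radii = np.arange(step_mm, max_radius_mm + step_mm / 2, step_mm)
    # world-mm points: (n_rays, n_samples, 3)
    pts = center[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    coords = (pts / np.asarray(vol.spacing)).reshape(-1, 3).T
    profiles = ndimage.map_coordinates(
        vol.voxels, coords, order=1, mode="nearest"
    ).reshape(n_rays, radii.size)
    center_hu = float(
        ndimage.map_coordinates(
            vol.voxels, (center / np.asarray(vol.spacing))[:, None], order=1
        )[0]
    )

    inner = np.full(n_rays, np.nan)
    outer = np.full(n_rays, np.nan)
    for k in range(n_rays):
        r_in, r_out = _detect_wall(
            profiles[k], radii, center_hu, step_mm, min_contrast_hu
        )
        inner[k], outer[k] = r_in, r_out

    n_missing = int(np.isnan(inner).sum())
    if n_missing > missing_ray_tolerance * n_rays:
        return WallCrossSection(
            center_mm=center,
            normal=np.asarray(normal, float),
            inner_radii_mm=inner,
            outer_radii_mm=outer,
            lumen_perimeter_mm=float("nan"),
            wall_area_mm2=float("nan"),
            status="excluded",
            exclusion_reason="wall_detection_failed",
            generation_label=generation_label,
            bifurcation_distance_mm=bifurcation_distance_mm,
        )

    inner_f = _interpolate_missing(inner, thetas)
    outer_f = _interpolate_missing(outer, thetas)

    pi = _polygon_perimeter(inner_f, thetas)
    area_in = _polygon_area(inner_f, thetas)
    area_out = _polygon_area(outer_f, thetas)
    wa = area_out - area_in
    return WallCrossSection(
        center_mm=center,
        normal=np.asarray(normal, float),
        inner_radii_mm=inner,
        outer_radii_mm=outer,
        lumen_perimeter_mm=float(pi),
        wall_area_mm2=float(wa),
        status="valid",
        generation_label=generation_label,
        bifurcation_distance_mm=bifurcation_distance_mm,
    )


def _detect_wall(profile, radii, center_hu, step_mm, min_contrast_hu):
    """FWHM-style inner/outer boundary radii on one radial HU profile."""
    peak_idx = int(np.argmax(profile))
    peak_val = float(profile[peak_idx])
    peak_r = radii[peak_idx]

    # lumen plateau: near-center samples (inside half the peak distance,
    # capped at 1 mm from the center at minimum to survive tiny lumens)
    lum_r = max(0.3, 0.5 * peak_r)
    lum_sel = radii <= lum_r
    lumen_level = float(np.median(np.concatenate([[center_hu], profile[lum_sel]])))

    if peak_val - lumen_level < min_contrast_hu:
        return np.nan, np.nan
    if peak_idx >= radii.size - max(2, int(0.5 / step_mm)):
        return np.nan, np.nan  # peak at the ray end; no room for the outer fall

    # parenchyma plateau: 1-3 mm beyond the peak
    par_sel = (radii >= peak_r + 1.0) & (radii <= peak_r + 3.0)
    if not par_sel.any():
        par_sel = radii > peak_r
    parench_level = float(np.median(profile[par_sel]))
    if peak_val - parench_level < min_contrast_hu / 2:
        return np.nan, np.nan  # wall does not stand out against parenchyma

    half_in = 0.5 * (lumen_level + peak_val)
    r_in = _first_crossing_up(profile, radii, half_in, 0, peak_idx)
    half_out = 0.5 * (peak_val + parench_level)
    r_out = _first_crossing_down(profile, radii, half_out, peak_idx)
    if np.isnan(r_in) or np.isnan(r_out) or not (0 < r_in <= r_out):
        return np.nan, np.nan
    return r_in, r_out


def _first_crossing_up(profile, radii, level, lo, hi):
    for i in range(lo + 1, hi + 1):
        if profile[i - 1] < level <= profile[i]:
            f = (level - profile[i - 1]) / (profile[i] - profile[i - 1])
            return radii[i - 1] + f * (radii[i] - radii[i - 1])
    return np.nan


def _first_crossing_down(profile, radii, level, lo):
    for i in range(lo + 1, radii.size):
        if profile[i - 1] > level >= profile[i]:
            f = (profile[i - 1] - level) / (profile[i - 1] - profile[i])
            return radii[i - 1] + f * (radii[i] - radii[i - 1])
    return np.nan


def _interpolate_missing(r: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Angular (circular) linear interpolation of NaN ray radii."""
    out = r.copy()
    bad = np.isnan(out)
    if not bad.any():
        return out
    good = ~bad
    # wrap-around interpolation on the circle
    th_ext = np.concatenate([thetas[good], thetas[good] + 2 * np.pi])
    r_ext = np.concatenate([out[good], out[good]])
    out[bad] = np.interp(thetas[bad] + 2 * np.pi, th_ext, r_ext)
    return out


def _polygon_perimeter(r: np.ndarray, thetas: np.ndarray) -> float:
    x = r * np.cos(thetas)
    y = r * np.sin(thetas)
    dx = np.diff(np.append(x, x[0]))
    dy = np.diff(np.append(y, y[0]))
    return float(np.sum(np.hypot(dx, dy)))


def _polygon_area(r: np.ndarray, thetas: np.ndarray) -> float:
    x = r * np.cos(thetas)
    y = r * np.sin(thetas)
    x2 = np.append(x, x[0])
    y2 = np.append(y, y[0])
    return float(0.5 * abs(np.sum(x2[:-1] * y2[1:] - x2[1:] * y2[:-1])))


# ---------------------------------------------------------------------------
# 5. exclusion rules
# ---------------------------------------------------------------------------

def filter_cross_sections(
    sections: list[WallCrossSection],
    bifurcation_margin_mm: float = 2.0,
) -> tuple[list[WallCrossSection], Counter]:
    """Apply the automatic exclusion rules; return survivors and a tally.

    Excluded: trachea (generation 0), main bronchi (generation 1), sections
    within ``bifurcation_margin_mm`` of a bifurcation, and sections whose
    wall detection failed.
    """
    valid: list[WallCrossSection] = []
    tally: Counter = Counter()
    for s in sections:
        if s.generation_label == 0:
            tally["trachea"] += 1
        elif s.generation_label == 1:
            tally["main_bronchus"] += 1
        elif s.bifurcation_distance_mm < bifurcation_margin_mm:
            tally["branching_region"] += 1
        elif s.status == "excluded":
            tally["wall_detection_failed"] += 1
        else:
            valid.append(s)
    return valid, tally


# ---------------------------------------------------------------------------
# 6. Pi10 regression
# ---------------------------------------------------------------------------

@dataclass
class Pi10Result:
    """sqrt(WA)-vs-Pi regression summary; pi10 = intercept + 10*slope."""

    slope: float
    intercept: float
    pi10: float
    n_sections_used: int
    n_sections_excluded: dict = field(default_factory=dict)


def compute_pi10(
    sections: list[WallCrossSection],
    exclusion_tally: Counter | dict | None = None,
) -> Pi10Result:
    """OLS of sqrt(wall area) on lumen perimeter across valid sections."""
    pis = np.array([s.lumen_perimeter_mm for s in sections if s.status == "valid"])
    swa = np.array([s.sqrt_wall_area_mm for s in sections if s.status == "valid"])
    ok = np.isfinite(pis) & np.isfinite(swa)
    pis, swa = pis[ok], swa[ok]
    if pis.size < 2 or np.unique(pis).size < 2:
        raise DegenerateRegressionError(
            "Pi10 regression needs >= 2 sections with distinct lumen perimeters"
        )
    fit = stats.linregress(pis, swa)
    pi10 = fit.intercept + 10.0 * fit.slope
    return Pi10Result(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pi10=float(pi10),
        n_sections_used=int(pis.size),
        n_sections_excluded=dict(exclusion_tally or {}),
    )


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def analyze_airways(
    vol: CTVolume,
    seed_point_mm,
    section_spacing_mm: float = 1.0,
    n_rays: int = N_RAYS_DEFAULT,
    bifurcation_margin_mm: float = 2.0,
    prune_mm: float = 3.0,
) -> dict:
    """Full bronchial pipeline: segmentation -> tree -> sections -> Pi10.

    Returns a dict with the segmentation, tree, all measured sections, the
    exclusion tally and the :class:`Pi10Result` (None when the regression is
    degenerate, e.g. a single measurable branch of constant caliber).
    """
    seg = segment_lumen(vol, seed_point_mm)
    tree = extract_centerline(seg.mask, vol.spacing, seed_point_mm, prune_mm=prune_mm)
    sites = sample_cross_sections(tree, section_spacing_mm)
    sections = []
    for site in sites:
        if not vol.contains_world(site.center_mm):
            continue
        sections.append(
            measure_wall(
                vol,
                site.center_mm,
                site.normal,
                n_rays=n_rays,
                generation_label=site.generation_label,
                bifurcation_distance_mm=site.bifurcation_distance_mm,
            )
        )
    valid, tally = filter_cross_sections(sections, bifurcation_margin_mm)
    try:
        pi10 = compute_pi10(valid, tally)
    except DegenerateRegressionError:
        pi10 = None
    return {
        "segmentation": seg,
        "tree": tree,
        "sections": sections,
        "valid_sections": valid,
        "exclusion_tally": tally,
        "pi10": pi10,
    }
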