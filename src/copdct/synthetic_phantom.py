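"""Synthetic paired-phase CT phantoms with exact ground truth.

The phantom is a rectangular "lung" of uniform attenuation (more negative on
inspiration than on expiration, as expiration densifies lung tissue), into
which two kinds of structures are rasterized:

* **airway tubes** — straight cylinders with an air-filled lumen (default
  -1000 HU) and a soft-tissue wall (default 0 HU), described by world-mm
  endpoints, lumen radius and wall thickness.  Closed-form lumen perimeter
  (Pi = 2*pi*r) and wall area (WA = pi*((r+t)^2 - r^2)) are recorded as
  ground truth for the airway-measurement pipeline.
* **emphysema clusters** — spheres of destroyed parenchyma set to a very low
  attenuation (default -1000 HU) in the *inspiratory* phase only, placed by
  seeded rejection sampling inside the lung mask and trimmed so the affected
  voxel count hits the requested fraction exactly (up to one voxel).

Both phases share one voxel grid, so there is no registration problem.
Additive, independent, per-voxel Gaussian noise models scanner noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, GeometryError
from .volume import CTVolume

AIR_HU = -1000.0


@dataclass
class TubeSpec:
    """A straight airway segment: world-mm axis, lumen radius, wall thickness.

    ``generation_label`` follows the airway-tree convention: 0 = trachea,
    1 = main bronchus, >=2 = measurable bronchus.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    lumen_radius: float
    wall_thickness: float
    lumen_hu: float = AIR_HU
    wall_hu: float = 0.0
    generation_label: int = 2

    def __post_init__(self) -> None:
        if self.lumen_radius <= 0:
            raise ConfigurationError("lumen_radius: must be > 0")
        if self.wall_thickness <= 0:
            raise ConfigurationError("wall_thickness: must be > 0")
        if self.wall_hu <= self.lumen_hu:
            raise ConfigurationError("wall_hu: must exceed lumen_hu")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    @property
    def lumen_perimeter_mm(self) -> float:
        """Closed-form internal perimeter Pi = 2*pi*r."""
        return 2.0 * np.pi * self.lumen_radius

    @property
    def wall_area_mm2(self) -> float:
        """Closed-form wall area WA = pi*((r+t)^2 - r^2)."""
        r, t = self.lumen_radius, self.wall_thickness
        return np.pi * ((r + t) ** 2 - r**2)


@dataclass
class PhantomSpec:
    """Geometry and attenuation of a paired-phase phantom.

    ``emphysema_fraction`` is the target fraction of lung-mask voxels set
    below -950 HU in the inspiratory phase.  ``lung_hu_exp`` must be greater
    than or equal to ``lung_hu_insp`` (less negative: expiration densifies).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    lung_hu_insp: float = -860.0
    lung_hu_exp: float = -720.0
    emphysema_fraction: float = 0.0
    emphysema_hu: float = AIR_HU
    emphysema_cluster_radius_mm: float = 3.0
    noise_sd: float = 0.0
    tubes: list[TubeSpec] = field(default_factory=list)
    margin_voxels: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.emphysema_fraction <= 1.0):
            raise ConfigurationError("emphysema_fraction: must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing: must be positive")
        if self.lung_hu_exp < self.lung_hu_insp:
            raise ConfigurationError(
                "lung_hu_exp: must be >= lung_hu_insp (expiration densifies lung)"
            )
        if self.emphysema_hu >= -950.0:
            raise ConfigurationError("emphysema_hu: must be below -950 HU")


@dataclass
class TubeGroundTruth:
    lumen_perimeter_mm: float
    wall_area_mm2: float
    centerline_mm: np.ndarray  # (n, 3) polyline along the axis
    lumen_voxel_count: int
    generation_label: int
    lumen_radius_mm: float
    wall_thickness_mm: float


@dataclass
class PhantomGroundTruth:
    """Exact per-phantom truth, populated from closed forms at build time."""

    lung_mask: np.ndarray
    true_emphysema_fraction: float
    tubes: list[TubeGroundTruth]
    true_mld_insp: float
    true_mld_exp: float

    @property
    def true_ei_ratio(self) -> float:
        return self.true_mld_exp / self.true_mld_insp

    def to_json_dict(self) -> dict:
        return {
            "true_emphysema_fraction": self.true_emphysema_fraction,
            "true_mld_insp": self.true_mld_insp,
            "true_mld_exp": self.true_mld_exp,
            "true_ei_ratio": self.true_ei_ratio,
            "lung_voxel_count": int(self.lung_mask.sum()),
            "tubes": [
                {
                    "lumen_perimeter_mm": t.lumen_perimeter_mm,
                    "wall_area_mm2": t.wall_area_mm2,
                    "sqrt_wall_area_mm": float(np.sqrt(t.wall_area_mm2)),
                    "lumen_voxel_count": t.lumen_voxel_count,
                    "generation_label": t.generation_label,
                    "lumen_radius_mm": t.lumen_radius_mm,
                    "wall_thickness_mm": t.wall_thickness_mm,
                    "centerline_mm": np.asarray(t.centerline_mm).tolist(),
                }
                for t in self.tubes
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))


def _voxel_center_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize_tube(shape, spacing, tube: TubeSpec, supersample: int = 3):
    """Partial-volume lumen and wall fractions for one cylinder.

    Each voxel is subdivided ``supersample**3``-fold and the fraction of
    sub-samples falling inside the lumen / the wall annulus is returned.
    Graded boundary voxels emulate CT partial-volume averaging, which the
    sub-voxel wall detector relies on; a hard-edged rasterization would bias
    boundary positions outward on convex surfaces.
    """
    start = np.asarray(tube.start, float)
    end = np.asarray(tube.end, float)
    axis = end - start
    length = np.linalg.norm(axis)
    if length == 0:
        raise GeometryError("tube start and end coincide")
    u = axis / length

    r_out = tube.lumen_radius + tube.wall_thickness
    lo_mm = np.minimum(start, end) - r_out - spacing
    hi_mm = np.maximum(start, end) + r_out + spacing
    lo = np.maximum(np.floor(lo_mm / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 1, shape)
    if np.any(lo >= hi):
        raise GeometryError("tube lies entirely outside the grid")

    sub_axes = [np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)]
    gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1)

    k = supersample
    offs = (np.arange(k) + 0.5) / k - 0.5  # sub-voxel offsets in voxel units
    lumen_count = np.zeros(centers.shape[:-1], dtype=np.int32)
    wall_count = np.zeros(centers.shape[:-1], dtype=np.int32)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                pts = centers + np.asarray([ox, oy, oz]) * spacing - start
                t = pts @ u
                radial = pts - t[..., None] * u
                d2 = np.einsum("...k,...k->...", radial, radial)
                inside_len = (t >= 0) & (t <= length)
                lumen_count += inside_len & (d2 <= tube.lumen_radius**2)
                wall_count += (
                    inside_len & (d2 > tube.lumen_radius**2) & (d2 <= r_out**2)
                )
    n_sub = k**3
    f_lumen = np.zeros(shape, np.float32)
    f_wall = np.zeros(shape, np.float32)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    f_lumen[sl] = lumen_count / n_sub
    f_wall[sl] = wall_count / n_sub
    return f_lumen, f_wall


def _check_tube_inside(spec: PhantomSpec, tube: TubeSpec) -> None:
    """Axis must lie in the grid; the outer cylinder must clear it radially.

    Tubes may run border-to-border *along* their own axis (open ends at the
    grid faces are legitimate), but the wall may not be clipped sideways.
    """
    extent = (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing)
    start, end = np.asarray(tube.start, float), np.asarray(tube.end, float)
    if np.any(start < -1e-6) or np.any(start > extent + 1e-6) or np.any(
        end < -1e-6
    ) or np.any(end > extent + 1e-6):
        raise GeometryError("tube axis extends outside the grid")
    axis = end - start
    u = axis / np.linalg.norm(axis)
    # two perpendicular directions spanning the cross-sectional plane
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, a)
    p /= np.linalg.norm(p)
    q = np.cross(u, p)
    r_out = tube.lumen_radius + tube.wall_thickness
    for endpoint in (start, end):
        for d in (p, q, -p, -q):
            pt = endpoint + r_out * d
            if np.any(pt < -1e-6) or np.any(pt > extent + 1e-6):
                raise GeometryError(
                    "tube outer wall extends outside the grid; enlarge the grid "
                    "or shrink the tube"
                )


def generate_phantom(
    spec: PhantomSpec, seed: int | None = 0
) -> tuple[CTVolume, CTVolume, PhantomGroundTruth]:
    """Build paired inspiratory/expiratory volumes plus exact ground truth.

    Identical ``(spec, seed)`` pairs produce byte-identical volumes.  The
    emphysema pattern and noise both derive from a single
    ``numpy.random.default_rng(seed)`` stream.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, float)
    rng = np.random.default_rng(seed)

    for tube in spec.tubes:
        _check_tube_inside(spec, tube)

    tube_truths: list[TubeGroundTruth] = []
    insp = np.full(shape, spec.lung_hu_insp, dtype=np.float32)
    exp = np.full(shape, spec.lung_hu_exp, dtype=np.float32)

    # Composite all tubes: lumen fractions take precedence over walls so
    # connected lumens stay open across junctions (carina regions).
    F_lumen = np.zeros(shape, np.float32)
    F_wall = np.zeros(shape, np.float32)
    lumen_hu = spec.tubes[0].lumen_hu if spec.tubes else AIR_HU
    wall_hu = spec.tubes[0].wall_hu if spec.tubes else 0.0
    for tube in spec.tubes:
        if tube.lumen_hu != lumen_hu or tube.wall_hu != wall_hu:
            raise ConfigurationError(
                "all tubes in one phantom must share lumen_hu and wall_hu"
            )
        f_lumen, f_wall = _rasterize_tube(shape, spacing, tube)
        np.maximum(F_lumen, f_lumen, out=F_lumen)
        np.maximum(F_wall, f_wall, out=F_wall)
        lumen = f_lumen >= 0.5
        n_pts = max(int(np.ceil(tube.length_mm / min(spacing))) + 1, 2)
        centerline = np.linspace(tube.start, tube.end, n_pts)
        tube_truths.append(
            TubeGroundTruth(
                lumen_perimeter_mm=tube.lumen_perimeter_mm,
                wall_area_mm2=tube.wall_area_mm2,
                centerline_mm=centerline,
                lumen_voxel_count=int(lumen.sum()),
                generation_label=tube.generation_label,
                lumen_radius_mm=tube.lumen_radius,
                wall_thickness_mm=tube.wall_thickness,
            )
        )
    if spec.tubes:
        F_wall = np.minimum(F_wall, 1.0 - F_lumen)
        f_bg = 1.0 - F_lumen - F_wall
        for vol in (insp, exp):
            np.copyto(
                vol,
                (f_bg * vol + F_lumen * lumen_hu + F_wall * wall_hu).astype(np.float32),
            )

    # Lung mask: interior voxels (2-voxel margin) that are pure parenchyma —
    # any airway lumen/wall contribution (including partial-volume edges)
    # excludes a voxel, keeping the ground-truth MLD exact.
    mask = np.zeros(shape, bool)
    m = spec.margin_voxels
    mask[m : shape[0] - m, m : shape[1] - m, m : shape[2] - m] = True
    if spec.tubes:
        mask &= (F_lumen + F_wall) <= 0.0

    n_lung = int(mask.sum())
    target = int(round(spec.emphysema_fraction * n_lung))
    emph = np.zeros(shape, bool)
    if target > 0:
        emph = _place_emphysema(mask, spacing, spec.emphysema_cluster_radius_mm, target, rng)
        insp[emph] = spec.emphysema_hu
    n_emph = int(emph.sum())

    mld_insp = ((n_lung - n_emph) * spec.lung_hu_insp + n_emph * spec.emphysema_hu) / n_lung
    mld_exp = spec.lung_hu_exp

    if spec.noise_sd > 0:
        insp = insp + rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)
        exp = exp + rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)

    truth = PhantomGroundTruth(
        lung_mask=mask,
        true_emphysema_fraction=n_emph / n_lung if n_lung else 0.0,
        tubes=tube_truths,
        true_mld_insp=float(mld_insp),
        true_mld_exp=float(mld_exp),
    )
    vol_i = CTVolume(insp, tuple(spacing), "inspiratory")
    vol_e = CTVolume(exp, tuple(spacing), "expiratory")
    return vol_i, vol_e, truth


def _place_emphysema(mask, spacing, radius_mm, target, rng) -> np.ndarray:
    """Seeded rejection sampling of spherical clusters; exact voxel count.

    Spheres are dropped at uniformly sampled in-mask centers until the
    cumulative affected count reaches ``target``; the last sphere's voxels
    are trimmed (nearest-to-center first) so the total is exact.
    """
    shape = mask.shape
    idx = np.argwhere(mask)
    emph = np.zeros(shape, bool)
    r_vox = np.maximum(radius_mm / spacing, 1.0)
    count = 0
    guard = 0
    while count < target:
        guard += 1
        if guard > 10000:
            # fall back: flood remaining deterministic voxels
            remaining = np.argwhere(mask & ~emph)
            need = target - count
            sel = remaining[:need]
            emph[tuple(sel.T)] = True
            break
        c = idx[rng.integers(len(idx))]
        lo = np.maximum(np.floor(c - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c + r_vox).astype(int) + 1, shape)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        gx, gy, gz = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
        )
        d2 = (
            ((gx - c[0]) * spacing[0]) ** 2
            + ((gy - c[1]) * spacing[1]) ** 2
            + ((gz - c[2]) * spacing[2]) ** 2
        )
        sphere = d2 <= radius_mm**2
        new = sphere & mask[sub] & ~emph[sub]
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if count + n_new > target:
            # trim: keep the voxels nearest the cluster center
            need = target - count
            cand = np.argwhere(new)
            order = np.argsort(d2[new], kind="stable")[:need]
            keep = cand[order]
            new = np.zeros_like(new)
            new[tuple(keep.T)] = True
            n_new = need
        emph[sub] |= new
        count += n_new
    return emph
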