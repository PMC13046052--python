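"""Ray-traced forward projection and physics-based projection augmentation.

The forward model is monochromatic: HU volumes are converted to relative
electron density by a piecewise-linear anchor table, attenuation per mm is
density * mu_water_per_mm, and each detector pixel receives the exact line
integral of attenuation along the ray from the source to the pixel center.
The tracer walks the voxel grid with Siddon-style exact intersection
lengths (the volume is treated as piecewise constant over voxels).

Four augmentations emulate the main physical deviations from the ideal
line-integral model, applied in a fixed, recorded order:

    beam hardening  p -> p - beta * p**2          (concave distortion)
    scatter         add a low-frequency scattered intensity field (SPR)
    motion blur     rigid per-view vertical shift, Gaussian-distributed
    Poisson noise   photon counting at n0 photons per unblocked pixel

Each stage is the identity at its zero parameter, so the pure line-integral
model is recoverable stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile
import yaml
from numba import njit
from scipy import ndimage

from .geometry import AcquisitionGeometry
from .volumes import HUVolume, substream

#: (HU, relative electron density) anchors; clamped outside the range
DEFAULT_DENSITY_ANCHORS = ((-1000.0, 0.0), (0.0, 1.0), (300.0, 1.10), (1000.0, 1.55))


@dataclass
class DensityVolume:
    """Relative electron density grid (water = 1)."""

    values: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("densities must be >= 0")


@dataclass
class PhysicsConfig:
    mu_water_per_mm: float = 0.02
    beam_hardening_beta: float = 0.05
    scatter_spr: float = 0.2
    scatter_sigma_px: float = 40.0
    motion_sd_mm: float = 0.5
    photons_n0: float = 1e4
    seed: int = 0

    def __post_init__(self):
        for name in ("mu_water_per_mm", "beam_hardening_beta", "scatter_spr",
                     "scatter_sigma_px", "motion_sd_mm", "photons_n0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def ideal(cls, **kw) -> "PhysicsConfig":
        """All augmentations off: pure line integrals."""
        kw.setdefault("beam_hardening_beta", 0.0)
        kw.setdefault("scatter_spr", 0.0)
        kw.setdefault("motion_sd_mm", 0.0)
        kw.setdefault("photons_n0", 0.0)   # 0 photons = noise stage skipped
        return cls(**kw)


@dataclass
class ProjectionSet:
    images: np.ndarray                      # (n_views, rows, cols)
    kind: str                               # "line_integral" | "intensity"
    geometry: AcquisitionGeometry
    augmentations_applied: tuple = ()

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3 or self.images.shape[0] != self.geometry.n_views:
            raise ValueError("images must be (n_views, rows, cols) matching the geometry")
        if tuple(self.images.shape[1:]) != tuple(self.geometry.detector_shape):
            raise ValueError("image shape does not match detector_shape")

    def subset_views(self, views) -> "ProjectionSet":
        views = list(views)
        from dataclasses import replace as dc_replace
        geom = dc_replace(self.geometry, n_views=len(views))
        return ProjectionSet(self.images[views], self.kind, geom, self.augmentations_applied)


def hu_to_density(vol: HUVolume, anchors=DEFAULT_DENSITY_ANCHORS) -> DensityVolume:
    """Piecewise-linear HU -> relative electron density conversion."""
    anchors = np.asarray(anchors, dtype=np.float64)
    hu_pts, rho_pts = anchors[:, 0], anchors[:, 1]
    if np.any(np.diff(hu_pts) <= 0):
        raise ValueError("anchor HU values must be strictly increasing")
    rho = np.interp(vol.values, hu_pts, rho_pts)   # np.interp clamps at the ends
    return DensityVolume(rho, vol.voxel_size_mm, vol.origin_mm)


@njit(cache=True)
def _siddon_view(vals, x0, y0, z0, h, sx, sy, sz, row_mm, col_mm, out):  # pragma: no cover
    nx, ny, nz = vals.shape
    bx, by, bz = x0 + nx * h, y0 + ny * h, z0 + nz * h
    for r in range(row_mm.shape[0]):
        py = row_mm[r]
        for c in range(col_mm.shape[0]):
            px = col_mm[c]
            dx, dy, dz = px - sx, py - sy, 0.0 - sz
            tmin, tmax = 0.0, 1.0
            miss = False
            for (d, s, lo, hi) in ((dx, sx, x0, bx), (dy, sy, y0, by), (dz, sz, z0, bz)):
                if d == 0.0:
                    if s < lo or s > hi:
                        miss = True
                        break
                else:
                    t1 = (lo - s) / d
                    t2 = (hi - s) / d
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tmin:
                        tmin = t1
                    if t2 < tmax:
                        tmax = t2
            if miss or tmin >= tmax:
                out[r, c] = 0.0
                continue
            L = np.sqrt(dx * dx + dy * dy + dz * dz)
            # per-axis next-crossing parameters and increments
            INF = 1e300
            if dx != 0.0:
                dtx = abs(h / dx)
                i0 = int(np.floor((sx + tmin * dx - x0) / h))
                tx = ((i0 + 1) * h + x0 - sx) / dx if dx > 0 else (i0 * h + x0 - sx) / dx
                while tx <= tmin:
                    tx += dtx
            else:
                tx, dtx = INF, INF
            if dy != 0.0:
                dty = abs(h / dy)
                j0 = int(np.floor((sy + tmin * dy - y0) / h))
                ty = ((j0 + 1) * h + y0 - sy) / dy if dy > 0 else (j0 * h + y0 - sy) / dy
                while ty <= tmin:
                    ty += dty
            else:
                ty, dty = INF, INF
            if dz != 0.0:
                dtz = abs(h / dz)
                k0 = int(np.floor((sz + tmin * dz - z0) / h))
                tz = ((k0 + 1) * h + z0 - sz) / dz if dz > 0 else (k0 * h + z0 - sz) / dz
                while tz <= tmin:
                    tz += dtz
            else:
                tz, dtz = INF, INF
            acc = 0.0
            t = tmin
            while t < tmax - 1e-12:
                tn = tx
                if ty < tn:
                    tn = ty
                if tz < tn:
                    tn = tz
                if tn > tmax:
                    tn = tmax
                mid = 0.5 * (t + tn)
                ix = int(np.floor((sx + mid * dx - x0) / h))
                iy = int(np.floor((sy + mid * dy - y0) / h))
                iz = int(np.floor((sz + mid * dz - z0) / h))
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    acc += (tn - t) * L * vals[ix, iy, iz]
                if tx <= tn + 1e-15:
                    tx += dtx
                if ty <= tn + 1e-15:
                    ty += dty
                if tz <= tn + 1e-15:
                    tz += dtz
                t = tn
            out[r, c] = acc
    return out


def forward_project(dvol: DensityVolume, geom: AcquisitionGeometry, view: int,
                    mu_per_mm: float = 0.02) -> np.ndarray:
    """Line integrals of attenuation (density * mu_per_mm, mm^-1 * mm) for
    one view: one exact ray trace per detector pixel center.  Rays that miss
    the volume return 0.
    """
    src = geom.source_position(view)
    h = dvol.voxel_size_mm
    zmax = dvol.origin_mm[2] + (dvol.values.shape[2] - 0.5) * h
    if src[2] <= zmax:
        raise ValueError("degenerate geometry: source inside or behind the volume")
    row_mm, col_mm = geom.pixel_centers_mm()
    out = np.empty(geom.detector_shape, dtype=np.float64)
    # plane origin = face of voxel (0,0,0)
    x0, y0, z0 = dvol.origin_mm - h / 2.0
    _siddon_view(dvol.values, x0, y0, z0, h, src[0], src[1], src[2],
                 row_mm, col_mm, out)
    return out * mu_per_mm


def apply_beam_hardening(p: np.ndarray, beta: float) -> np.ndarray:
    """Quadratic concave distortion p - beta*p**2; beta = 0 is the identity."""
    p = np.asarray(p, dtype=np.float64)
    if beta == 0:
        return p.copy()
    pmax = float(p.max()) if p.size else 0.0
    if beta * pmax >= 0.5:
        raise ValueError(
            f"beam hardening not monotone: beta*max(p) = {beta * pmax:.3f} >= 0.5 "
            f"(attained max line integral {pmax:.3f})")
    return p - beta * p**2


def apply_scatter(p: np.ndarray, spr: float, sigma_px: float, n0: float = 1e4) -> np.ndarray:
    """Add a blurred scattered-intensity field at the given scatter-to-primary
    ratio and re-log: p' = -ln((P + spr*blur(P)) / n0) with P = n0*exp(-p)."""
    p = np.asarray(p, dtype=np.float64)
    if spr == 0:
        return p.copy()
    P = n0 * np.exp(-p)
    S = spr * ndimage.gaussian_filter(P, sigma=sigma_px, mode="nearest")
    return -np.log((P + S) / n0)


def apply_motion_blur(projections: np.ndarray, motion_sd_mm: float, seed: int,
                      pitch_mm: float) -> np.ndarray:
    """Rigid per-view vertical shift, Delta_v ~ N(0, motion_sd_mm), applied
    with linear interpolation and edge clamping; sd = 0 is the identity."""
    projections = np.asarray(projections, dtype=np.float64)
    if motion_sd_mm < 0:
        raise ValueError("motion SD must be >= 0")
    if motion_sd_mm == 0:
        return projections.copy()
    rng = np.random.default_rng(seed)
    shifts_mm = rng.normal(0.0, motion_sd_mm, projections.shape[0])
    out = np.empty_like(projections)
    for v in range(projections.shape[0]):
        out[v] = ndimage.shift(projections[v], (shifts_mm[v] / pitch_mm, 0.0),
                               order=1, mode="nearest")
    return out


def apply_poisson_noise(p: np.ndarray, n0: float, seed: int) -> np.ndarray:
    """Photon-counting noise: N ~ Poisson(n0*exp(-p)); p' = -ln(max(N,1)/n0)."""
    if n0 <= 0:
        raise ValueError("photon count n0 must be > 0")
    p = np.asarray(p, dtype=np.float64)
    rng = np.random.default_rng(seed)
    lam = n0 * np.exp(-p)
    N = rng.poisson(lam).astype(np.float64)
    return -np.log(np.maximum(N, 1.0) / n0)


def simulate_projections(vol: HUVolume, geom: AcquisitionGeometry,
                         physics: PhysicsConfig, *, center_at_iso: bool = True,
                         anchors=DEFAULT_DENSITY_ANCHORS) -> ProjectionSet:
    """Full simulation pipeline for one patient volume.

    hu_to_density -> forward_project (all views) -> beam hardening ->
    scatter -> motion blur -> Poisson noise, in this fixed order; each stage
    with a zero parameter is skipped (identity).  With ``center_at_iso`` the
    volume is placed so its center sits on the mid-patient plane
    (0, 0, patient_offset_mm).
    """
    if center_at_iso:
        vol = vol.recentered((0.0, 0.0, geom.patient_offset_mm))
    dvol = hu_to_density(vol, anchors)
    images = np.stack([forward_project(dvol, geom, v, physics.mu_water_per_mm)
                       for v in range(geom.n_views)])
    applied = ["ray_trace"]
    if physics.beam_hardening_beta > 0:
        images = apply_beam_hardening(images, physics.beam_hardening_beta)
        applied.append("beam_hardening")
    if physics.scatter_spr > 0:
        n0 = physics.photons_n0 if physics.photons_n0 > 0 else 1e4
        images = apply_scatter(images, physics.scatter_spr,
                               physics.scatter_sigma_px, n0)
        applied.append("scatter")
    if physics.motion_sd_mm > 0:
        images = apply_motion_blur(images, physics.motion_sd_mm,
                                   substream(physics.seed, "physics").integers(2**31),
                                   geom.detector_pitch_mm)
        applied.append("motion_blur")
    if physics.photons_n0 > 0:
        images = apply_poisson_noise(images, physics.photons_n0,
                                     substream(physics.seed, "physics").integers(2**31) + 1)
        applied.append("poisson_noise")
    return ProjectionSet(images, "line_integral", geom, tuple(applied))


def save_projections(pset: ProjectionSet, tiff_path, physics: PhysicsConfig | None = None) -> None:
    """Multi-page float32 TIFF plus a YAML sidecar with geometry/physics."""
    tifffile.imwrite(str(tiff_path), pset.images.astype(np.float32))
    meta = {
        "kind": pset.kind,
        "augmentations_applied": list(pset.augmentations_applied),
        "geometry": _plain(asdict(pset.geometry)),
    }
    if physics is not None:
        meta["physics"] = _plain(asdict(physics))
    with open(str(tiff_path) + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_projections(tiff_path) -> ProjectionSet:
    images = tifffile.imread(str(tiff_path)).astype(np.float64)
    with open(str(tiff_path) + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    g = meta["geometry"]
    g["sweep_deg"] = tuple(g["sweep_deg"])
    g["detector_shape"] = tuple(g["detector_shape"])
    geom = AcquisitionGeometry(**g)
    return ProjectionSet(images, meta["kind"], geom, tuple(meta["augmentations_applied"]))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
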