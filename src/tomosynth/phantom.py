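"""Seeded generator of chest-like HU phantoms with aligned ground-truth labels.

The phantom is a stylized thorax built from analytic solids painted in a
fixed order (background -> soft-tissue body -> lungs -> bone -> nodules;
later regions overwrite earlier ones).  Region membership is decided at
voxel centers with no partial-volume antialiasing, so an independent
point-in-geometry test over voxel centers reproduces the volume exactly.

Local frame: the grid is centered on the origin; x lateral, y vertical
(cranio-caudal), z depth (posterior at negative z).  The spine runs
vertically at the posterior midline; ribs are circular torus arcs around
the lungs; nodules are small soft-tissue spheres, typically inside a lung.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .tissue import DEFAULT_SCHEME, TissueScheme, segment_hu_array
from .volumes import HU_FLOOR, HUVolume, LabelVolume, substream

DEFAULT_HU = {
    "background": -1000.0,
    "body": 40.0,
    "lung": -850.0,
    "bone": 700.0,
    "nodule": 20.0,
}


@dataclass
class PhantomSpec:
    grid_shape: tuple = (48, 48, 48)              # (nx, ny, nz) voxels
    voxel_size_mm: float = 3.0
    body_halfaxes_mm: tuple | None = (60.0, 66.0, 48.0)
    lung_halfaxes_mm: tuple | None = (22.0, 40.0, 28.0)
    lung_offsets_mm: tuple = ((-28.0, 4.0, 4.0), (28.0, 4.0, 4.0))
    spine_radius_mm: float = 9.0
    n_ribs: int = 4
    nodules: tuple = ()                           # ((center_mm, radius_mm), ...)
    hu_values: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    seed: int = 0

    def __post_init__(self):
        hu = self.hu_values
        scheme = DEFAULT_SCHEME
        for k in ("background", "lung"):
            if hu[k] >= scheme.air_below_hu:
                raise ValueError(f"{k} HU must class as air (< {scheme.air_below_hu})")
        for k in ("body", "nodule"):
            if not (scheme.air_below_hu < hu[k] < scheme.bone_above_hu):
                raise ValueError(f"{k} HU must class as soft tissue")
        if hu["bone"] <= scheme.bone_above_hu:
            raise ValueError(f"bone HU must class as bone (> {scheme.bone_above_hu})")
        if min(hu.values()) < HU_FLOOR:
            raise ValueError(f"HU values must be >= {HU_FLOOR}")
        if self.spine_radius_mm < 0:
            raise ValueError("spine radius must be >= 0")
        for _, r in self.nodules:
            if r <= 0:
                raise ValueError("nodule radii must be positive")
        half = self.half_extent_mm
        if self.body_halfaxes_mm is not None:
            A = np.asarray(self.body_halfaxes_mm, float)
            if np.any(A <= 0):
                raise ValueError("body half-axes must be positive")
            if np.any(A > half):
                raise ValueError("body exceeds grid bounds")
            if self.lung_halfaxes_mm is not None:
                a = np.asarray(self.lung_halfaxes_mm, float)
                if np.any(a <= 0):
                    raise ValueError("lung half-axes must be positive")
                for off in self.lung_offsets_mm:
                    if not _ellipsoid_inside(np.asarray(off, float), a, A):
                        raise ValueError("lungs must lie strictly inside the body")
        elif self.lung_halfaxes_mm is not None or self.n_ribs or self.spine_radius_mm:
            raise ValueError("lungs/bone require a body")
        for c, r in self.nodules:
            if np.any(np.abs(np.asarray(c, float)) + r > half):
                raise ValueError("nodule exceeds grid bounds")

    @property
    def half_extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * self.voxel_size_mm / 2.0


def _ellipsoid_inside(center, halfaxes, outer_halfaxes, n_probe=512) -> bool:
    """Numerical check that an ellipsoid lies strictly inside another
    (both axis-aligned, outer centered at the origin): probes a Fibonacci
    sphere of surface points against the outer quadratic form."""
    k = np.arange(n_probe)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    cz = 1 - 2 * (k + 0.5) / n_probe
    s = np.sqrt(1 - cz**2)
    pts = center + halfaxes * np.stack([s * np.cos(phi), s * np.sin(phi), cz], axis=1)
    q = np.sum((pts / outer_halfaxes) ** 2, axis=1)
    return bool(np.all(q < 1.0))


def _voxel_center_grid(spec: PhantomSpec):
    axes = [(np.arange(n) - (n - 1) / 2.0) * spec.voxel_size_mm for n in spec.grid_shape]
    return np.meshgrid(*axes, indexing="ij")


def rib_parameters(spec: PhantomSpec) -> list:
    """Seeded rib geometry: list of (height_mm, major_radius_mm, tube_radius_mm).

    Heights are spread over the central 60% of the body's vertical extent
    with a small seeded jitter; the major radius follows the body's
    cross-section shrink at that height so ribs stay inside the body.
    """
    if spec.body_halfaxes_mm is None or spec.n_ribs == 0:
        return []
    rng = substream(spec.seed, "phantom")
    A = np.asarray(spec.body_halfaxes_mm, float)
    ys = np.linspace(-0.55, 0.55, spec.n_ribs) * A[1]
    ribs = []
    tube = 0.35 * spec.spine_radius_mm if spec.spine_radius_mm > 0 else 3.0
    for y0 in ys:
        y = y0 + rng.normal(0.0, 0.02 * A[1])
        y = float(np.clip(y, -0.6 * A[1], 0.6 * A[1]))
        shrink = np.sqrt(max(1.0 - (y / A[1]) ** 2, 0.0))
        major = 0.7 * min(A[0], A[2]) * shrink * (1.0 + rng.uniform(-0.03, 0.03))
        ribs.append((y, float(major), float(tube)))
    return ribs


def make_phantom(spec: PhantomSpec) -> tuple:
    """Render a PhantomSpec into aligned (HUVolume, LabelVolume).

    Painting order is background -> body -> lungs -> bone (spine, ribs)
    -> nodules; overlapping regions resolve to the last-painted one.  The
    label volume is the tissue-class map of the configured region HU values,
    identical to ``tissue.segment_hu`` of the returned HU volume.
    """
    X, Y, Z = _voxel_center_grid(spec)
    region = np.zeros(spec.grid_shape, dtype=np.uint8)   # region ids below
    hu_of_region = [spec.hu_values["background"], spec.hu_values["body"],
                    spec.hu_values["lung"], spec.hu_values["bone"],
                    spec.hu_values["nodule"]]

    if spec.body_halfaxes_mm is not None:
        A = np.asarray(spec.body_halfaxes_mm, float)
        body = (X / A[0]) ** 2 + (Y / A[1]) ** 2 + (Z / A[2]) ** 2 < 1.0
        region[body] = 1
        if spec.lung_halfaxes_mm is not None:
            a = np.asarray(spec.lung_halfaxes_mm, float)
            for off in spec.lung_offsets_mm:
                lung = (((X - off[0]) / a[0]) ** 2 + ((Y - off[1]) / a[1]) ** 2
                        + ((Z - off[2]) / a[2]) ** 2) < 1.0
                region[lung] = 2
        if spec.spine_radius_mm > 0:
            z_sp = -0.5 * A[2]
            spine = (X**2 + (Z - z_sp) ** 2 < spec.spine_radius_mm**2) \
                & (np.abs(Y) < 0.8 * A[1]) & body
            region[spine] = 3
        for y0, major, tube in rib_parameters(spec):
            # bone is clipped to the body: rib tubes never poke into background
            rib = ((np.sqrt(X**2 + Z**2) - major) ** 2 + (Y - y0) ** 2 < tube**2) & body
            region[rib] = 3
    for center, radius in spec.nodules:
        c = np.asarray(center, float)
        nod = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 < radius**2
        region[nod] = 4

    hu = np.asarray(hu_of_region, dtype=np.float64)[region]
    origin = -(np.asarray(spec.grid_shape, float) - 1) / 2.0 * spec.voxel_size_mm
    hu_vol = HUVolume(hu, spec.voxel_size_mm, origin)
    labels = LabelVolume(segment_hu_array(hu), spec.voxel_size_mm, origin)
    return hu_vol, labels


def perturb_phantom(volume: HUVolume, noise_sd_hu: float, seed: int) -> HUVolume:
    """Add seeded Gaussian HU noise (clipped at the HU floor).

    Makes the segmentation task non-trivial near the class thresholds;
    ``noise_sd_hu = 0`` is the identity.
    """
    if noise_sd_hu < 0:
        raise ValueError("noise SD must be >= 0")
    if noise_sd_hu == 0:
        return HUVolume(volume.values.copy(), volume.voxel_size_mm, volume.origin_mm)
    rng = np.random.default_rng(seed)
    noisy = volume.values + rng.normal(0.0, noise_sd_hu, volume.values.shape)
    return HUVolume(np.maximum(noisy, HU_FLOOR), volume.voxel_size_mm, volume.origin_mm)


def sample_spec(seed: int, grid_shape=(48, 48, 48), voxel_size_mm: float = 3.0) -> PhantomSpec:
    """Draw a randomized patient phantom: body/lung sizes, lung offsets,
    rib count and 0-2 lung nodules all vary with the seed.

    Sizes scale with the grid so the body fills most of the field of view,
    as a thorax does in a chest acquisition.
    """
    rng = substream(seed, "spec")
    half = np.asarray(grid_shape, float) * voxel_size_mm / 2.0
    A = half * np.array([rng.uniform(0.72, 0.92),
                         rng.uniform(0.82, 0.97),
                         rng.uniform(0.58, 0.78)])
    lung = A * np.array([rng.uniform(0.30, 0.40),
                         rng.uniform(0.52, 0.66),
                         rng.uniform(0.50, 0.64)])
    dx = A[0] * rng.uniform(0.42, 0.50)
    dy = A[1] * rng.uniform(0.0, 0.10)
    dz = A[2] * rng.uniform(0.05, 0.16)
    nodules = []
    for _ in range(rng.integers(0, 3)):
        side = rng.choice([-1.0, 1.0])
        center = (side * dx + rng.uniform(-0.3, 0.3) * lung[0],
                  dy + rng.uniform(-0.4, 0.4) * lung[1],
                  dz + rng.uniform(-0.3, 0.3) * lung[2])
        nodules.append((tuple(float(c) for c in center),
                        float(rng.uniform(1.5, 2.5) * voxel_size_mm)))
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=voxel_size_mm,
        body_halfaxes_mm=tuple(A),
        lung_halfaxes_mm=tuple(lung),
        lung_offsets_mm=((-dx, dy, dz), (dx, dy, dz)),
        spine_radius_mm=float(rng.uniform(0.10, 0.14) * min(A[0], A[2])),
        n_ribs=int(rng.integers(3, 6)),
        nodules=tuple(nodules),
        seed=int(seed),
    )


def save_spec(spec: PhantomSpec, path) -> None:
    d = asdict(spec)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(d), fh)


def load_spec(path) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("grid_shape", "body_halfaxes_mm", "lung_halfaxes_mm"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("lung_offsets_mm") is not None:
        d["lung_offsets_mm"] = tuple(tuple(o) for o in d["lung_offsets_mm"])
    d["nodules"] = tuple((tuple(c), float(r)) for c, r in (d.get("nodules") or ()))
    return PhantomSpec(**d)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
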