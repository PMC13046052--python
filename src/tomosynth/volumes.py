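"""Volumetric containers shared across the pipeline.

Axis convention (right-handed, mm units, 0-based indices):
    axis 0 = x = lateral  (sagittal-slice index axis)
    axis 1 = y = vertical (tube-sweep axis)
    axis 2 = z = depth    (beam axis; the detector lies in the plane z = 0)

``origin_mm`` is the world position of the *center* of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

#: fixed tissue-class order used for every tensor, matrix and loss weight
CLASS_NAMES = ("air", "soft", "bone")
AIR, SOFT, BONE = 0, 1, 2

#: floor of the Hounsfield scale as stored here
HU_FLOOR = -1024.0

# named sub-streams hanging off the single global seed
_STREAMS = {"phantom": 1, "physics": 2, "split": 3, "train": 4, "spec": 5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random sub-stream derived from a global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


def derive_seed(seed: int, name: str) -> int:
    """Deterministic child seed (< 2**31) for APIs that take an integer."""
    return int(np.random.SeedSequence([int(seed), _STREAMS[name]]).generate_state(1)[0] % (2**31))


@dataclass
class HUVolume:
    """3D scalar grid in Hounsfield units with isotropic-per-axis spacing."""

    values: np.ndarray                 # (nx, ny, nz) float
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("HUVolume requires a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        if self.values.size and self.values.min() < HU_FLOOR:
            raise ValueError(f"HU values must be >= {HU_FLOOR}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm * np.arange(n)

    def recentered(self, center_mm) -> "HUVolume":
        """Copy with the grid center moved to ``center_mm`` (world frame)."""
        half = (np.array(self.values.shape) - 1) / 2.0 * self.voxel_size_mm
        return replace(self, origin_mm=np.asarray(center_mm, float) - half)


@dataclass
class LabelVolume:
    """Categorical air/soft/bone grid aligned with an HUVolume."""

    values: np.ndarray                 # (nx, ny, nz) uint8 in {0,1,2}
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")
        if self.values.size and not np.isin(np.unique(self.values), [AIR, SOFT, BONE]).all():
            raise ValueError("labels must be in {0 (air), 1 (soft), 2 (bone)}")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _affine(voxel_size_mm: float, origin_mm: np.ndarray) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def save_nifti(vol, path) -> None:
    """Write an HUVolume (float32) or LabelVolume (uint8) as NIfTI."""
    if isinstance(vol, LabelVolume):
        data = vol.values.astype(np.uint8)
        img = nib.Nifti1Image(data, _affine(vol.voxel_size_mm, vol.origin_mm))
        img.header["intent_name"] = b"airsoftbone"
    else:
        data = vol.values.astype(np.float32)
        img = nib.Nifti1Image(data, _affine(vol.voxel_size_mm, vol.origin_mm))
    nib.save(img, str(path))


def load_nifti(path, kind: str = "hu"):
    """Read a NIfTI written by :func:`save_nifti` (kind: 'hu' | 'labels')."""
    img = nib.load(str(path))
    aff = img.affine
    voxel = float(aff[0, 0])
    origin = np.asarray(aff[:3, 3], dtype=float)
    data = np.asarray(img.dataobj)
    if kind == "labels":
        return LabelVolume(data.astype(np.uint8), voxel, origin)
    return HUVolume(np.asarray(data, dtype=np.float64), voxel, origin)
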