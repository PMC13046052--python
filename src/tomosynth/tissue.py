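"""The three-class tissue surrogate: HU <-> {air, soft, bone} conversions.

Thresholds follow the usual chest-CT reading: everything below -800 HU is
air (lung parenchyma included), everything at or above 300 HU is bone, the
rest is soft tissue.  The class boundaries are half-open so the partition is
total: -800 HU classes as soft, 300 HU as bone.  Representative values
(-1000 / 0 / 500 HU) convert label maps back to CT-like images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import AIR, BONE, SOFT, HUVolume, LabelVolume


@dataclass(frozen=True)
class TissueScheme:
    air_below_hu: float = -800.0
    bone_above_hu: float = 300.0
    representative_hu: tuple = (-1000.0, 0.0, 500.0)   # (air, soft, bone)

    def __post_init__(self):
        if not self.air_below_hu < self.bone_above_hu:
            raise ValueError("air threshold must lie below the bone threshold")
        rep_air, rep_soft, rep_bone = self.representative_hu
        if not (rep_air < self.air_below_hu
                and self.air_below_hu <= rep_soft < self.bone_above_hu
                and rep_bone >= self.bone_above_hu):
            raise ValueError("representative HU values must fall inside their class intervals")


DEFAULT_SCHEME = TissueScheme()


def segment_hu(vol: HUVolume, scheme: TissueScheme = DEFAULT_SCHEME) -> LabelVolume:
    """Threshold an HU volume into air / soft / bone labels.

    air:  HU < air_below_hu        (default -800)
    soft: air_below_hu <= HU < bone_above_hu
    bone: HU >= bone_above_hu      (default 300)
    """
    hu = vol.values
    labels = np.full(hu.shape, SOFT, dtype=np.uint8)
    labels[hu < scheme.air_below_hu] = AIR
    labels[hu >= scheme.bone_above_hu] = BONE
    return LabelVolume(labels, vol.voxel_size_mm, vol.origin_mm)


def segment_hu_array(hu: np.ndarray, scheme: TissueScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Array-in/array-out variant of :func:`segment_hu` (any shape)."""
    labels = np.full(hu.shape, SOFT, dtype=np.uint8)
    labels[hu < scheme.air_below_hu] = AIR
    labels[hu >= scheme.bone_above_hu] = BONE
    return labels


def labels_to_hu(labels: LabelVolume, scheme: TissueScheme = DEFAULT_SCHEME) -> HUVolume:
    """Map labels to their representative HU values (-1000 / 0 / 500)."""
    return HUVolume(labels_to_hu_array(labels.values, scheme),
                    labels.voxel_size_mm, labels.origin_mm)


def labels_to_hu_array(labels: np.ndarray, scheme: TissueScheme = DEFAULT_SCHEME) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.size and not np.isin(np.unique(lab), [AIR, SOFT, BONE]).all():
        raise ValueError("unknown label value")
    lut = np.asarray(scheme.representative_hu, dtype=np.float64)
    return lut[lab.astype(np.intp)]


def probs_to_labels(probs: np.ndarray, *, tol: float = 1e-5) -> np.ndarray:
    """Per-pixel argmax over class probabilities; ties break toward the
    earlier class in the fixed (air, soft, bone) order.

    ``probs`` has the class axis last and must sum to 1 per pixel.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[-1] != 3:
        raise ValueError("expected 3 class channels on the last axis")
    if np.any(probs < 0):
        raise ValueError("probabilities must be non-negative")
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValueError("per-pixel probabilities must sum to 1")
    # np.argmax returns the first maximal index, which is the documented tie-break
    return np.argmax(probs, axis=-1).astype(np.uint8)
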