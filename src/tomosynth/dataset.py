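"""Aligned (projection patch-stack, sagittal label slice) training pairs.

Because input projections and target CT slices are generated from the same
volume under a known geometry, every emitted pair is aligned by
construction — the property that makes supervised training possible at all
for this modality.  Patient-level splits guard against leakage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict

import h5py
import numpy as np
import yaml

from .geometry import AcquisitionGeometry
from .phantom import PhantomSpec, make_phantom
from .projector import PhysicsConfig, ProjectionSet, simulate_projections
from .volumes import LabelVolume, derive_seed, substream


@dataclass
class PatchStack:
    """(n_views, rows, strip_width) stack of line-integral strips for one
    sagittal plane; the model input."""

    values: np.ndarray
    slice_x_mm: float
    geometry: AcquisitionGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.detector_shape[0],
                    self.geometry.strip_width_px)
        if self.values.shape != expected:
            raise ValueError(f"patch shape {self.values.shape} != geometry contract {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("patch values must be finite")


@dataclass
class SamplePair:
    input: PatchStack
    target: np.ndarray          # (rows_out, depth_out) uint8 labels
    patient_id: str
    slice_index: int


@dataclass
class SplitSpec:
    """Patient-level train/val/test partition.  ``fractions`` mirror the
    full-scale study proportions by default (2467/250/250 of 2967)."""

    fractions: tuple = (2467 / 2967, 250 / 2967, 250 / 2967)
    counts: tuple | None = None          # absolute (train, val, test); overrides fractions
    seed: int = 0


def extract_patch(projections: ProjectionSet, slice_x_mm: float) -> PatchStack:
    """Gather one sagittal plane's strip columns from every view.

    Columns falling off the detector edge are zero-padded so the
    (n_views, rows, strip_width) contract always holds; a strip entirely
    off the detector is an error (raised by the geometry).
    """
    geom = projections.geometry
    cols = geom.strip_columns(slice_x_mm)
    ncols = geom.detector_shape[1]
    out = np.zeros((geom.n_views, geom.detector_shape[0], geom.strip_width_px))
    valid = (cols >= 0) & (cols < ncols)
    out[:, :, valid] = projections.images[:, :, cols[valid]]
    return PatchStack(out, slice_x_mm, geom)


def target_slice(labels: LabelVolume, slice_index: int, out_shape=None) -> np.ndarray:
    """Sagittal label plane (vertical x depth), nearest-neighbor resampled.

    Resampling phase starts at index 0: out[j] = in[floor(j * n_in / n_out)],
    so downsampling by 2 takes every other voxel starting at 0.
    """
    nx = labels.values.shape[0]
    if not 0 <= slice_index < nx:
        raise IndexError(f"slice index {slice_index} out of range [0, {nx})")
    plane = labels.values[slice_index]          # (ny, nz)
    if out_shape is None or tuple(out_shape) == plane.shape:
        return plane.copy()
    iy = (np.arange(out_shape[0]) * plane.shape[0]) // out_shape[0]
    iz = (np.arange(out_shape[1]) * plane.shape[1]) // out_shape[1]
    return plane[np.ix_(iy, iz)]


def slice_x_mm_of_index(labels: LabelVolume, slice_index: int) -> float:
    """World lateral coordinate of a sagittal slice center."""
    return float(labels.origin_mm[0] + slice_index * labels.voxel_size_mm)


def split_patients(ids, spec: SplitSpec) -> tuple:
    """Seeded shuffle then partition into disjoint, exhaustive
    (train, val, test) id lists."""
    ids = list(ids)
    n = len(ids)
    if spec.counts is not None:
        n_train, n_val, n_test = spec.counts
        if n_train + n_val + n_test != n:
            raise ValueError(f"counts {spec.counts} do not sum to {n} patients")
    else:
        n_train = int(round(spec.fractions[0] * n))
        n_val = int(round(spec.fractions[1] * n))
        n_test = n - n_train - n_val
        if min(n_train, n_val, n_test) < 0:
            raise ValueError("infeasible split fractions")
    rng = substream(spec.seed, "split")
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    train = shuffled[:n_train]
    val = shuffled[n_train:n_train + n_val]
    test = shuffled[n_train + n_val:]
    assert set(train) | set(val) | set(test) == set(ids)
    assert not (set(train) & set(val) or set(train) & set(test) or set(val) & set(test))
    return train, val, test


def audit_pair_alignment(pair: SamplePair, labels: LabelVolume,
                         patient_offset_mm: float) -> bool:
    """Geometric audit: forward-project the target slice's bone voxels and
    check they land inside the pair's strip window on every view."""
    geom = pair.input.geometry
    x_mm = pair.input.slice_x_mm
    cols = geom.strip_columns(x_mm)
    plane = labels.values[pair.slice_index]
    ys, zs = np.nonzero(plane == 2)
    if ys.size == 0:
        return True
    y_mm = labels.origin_mm[1] + ys * labels.voxel_size_mm
    z_mm = patient_offset_mm - (labels.values.shape[2] - 1) / 2 * labels.voxel_size_mm \
        + zs * labels.voxel_size_mm
    for view in (0, geom.n_views - 1):
        for y, z in zip(y_mm, z_mm):
            _, col_mm = geom.project_point(view, (x_mm, y, z))
            px = int(round(geom.col_mm_to_px(col_mm)))
            if not cols[0] <= px <= cols[-1]:
                return False
    return True


# ----------------------------------------------------------------------------
# dataset building


def default_slice_indices(nx: int, n_slices: int) -> np.ndarray:
    """Evenly spread sagittal indices over the central 30% of the lateral
    extent: the band crossing both lungs and the spine, so every tissue
    class is represented in the targets."""
    if n_slices == 1:
        return np.array([nx // 2])
    return np.unique((np.linspace(0.35, 0.65, n_slices) * nx).round().astype(int))


def build_samples(specs, geom: AcquisitionGeometry, physics: PhysicsConfig,
                  out_shape=(32, 32), slices_per_patient: int = 2,
                  noise_sd_hu: float = 0.0):
    """Simulate each phantom once and emit SamplePairs for a configured
    subset of sagittal slices.  Returns (samples, per-patient label volumes).
    """
    from dataclasses import replace as dc_replace
    from .phantom import perturb_phantom

    samples, label_map = [], {}
    for spec in specs:
        pid = f"P{spec.seed:05d}"
        hu, labels = make_phantom(spec)
        if noise_sd_hu > 0:
            hu = perturb_phantom(hu, noise_sd_hu, derive_seed(spec.seed, "phantom"))
        phys = dc_replace(physics, seed=derive_seed(spec.seed, "physics"))
        pset = simulate_projections(hu, geom, phys)
        labels_iso = LabelVolume(labels.values, labels.voxel_size_mm, labels.origin_mm)
        label_map[pid] = labels_iso
        for idx in default_slice_indices(labels.values.shape[0], slices_per_patient):
            x_mm = slice_x_mm_of_index(labels, int(idx))
            patch = extract_patch(pset, x_mm)
            target = target_slice(labels, int(idx), out_shape)
            samples.append(SamplePair(patch, target, pid, int(idx)))
    return samples, label_map


def save_shard(samples, path, geom: AcquisitionGeometry, physics: PhysicsConfig,
               seed: int) -> dict:
    """Persist SamplePairs to an HDF5 shard; returns the manifest dict
    (also written as ``<path>.manifest.yaml``)."""
    inputs = np.stack([s.input.values for s in samples]).astype(np.float32)
    targets = np.stack([s.target for s in samples]).astype(np.uint8)
    pids = np.array([s.patient_id for s in samples], dtype="S16")
    slice_idx = np.array([s.slice_index for s in samples], dtype=np.int32)
    slice_x = np.array([s.input.slice_x_mm for s in samples], dtype=np.float64)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("inputs", data=inputs, compression="gzip")
        fh.create_dataset("targets", data=targets, compression="gzip")
        fh.create_dataset("patient_ids", data=pids)
        fh.create_dataset("slice_indices", data=slice_idx)
        fh.create_dataset("slice_x_mm", data=slice_x)
    manifest = {
        "n_samples": len(samples),
        "seed": int(seed),
        "geometry": _plain(asdict(geom)),
        "physics": _plain(asdict(physics)),
        "checksums": {
            "inputs": hashlib.sha256(inputs.tobytes()).hexdigest(),
            "targets": hashlib.sha256(targets.tobytes()).hexdigest(),
        },
    }
    with open(str(path) + ".manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest


def load_shard(path):
    """Load a shard back into (inputs, targets, patient_ids, slice_indices,
    slice_x_mm) arrays plus its manifest."""
    with h5py.File(path, "r") as fh:
        inputs = fh["inputs"][...]
        targets = fh["targets"][...]
        pids = [p.decode() for p in fh["patient_ids"][...]]
        slice_idx = fh["slice_indices"][...]
        slice_x = fh["slice_x_mm"][...]
    with open(str(path) + ".manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return inputs, targets, pids, slice_idx, slice_x, manifest


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
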