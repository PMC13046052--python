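"""Volume reassembly from slice predictions and quantitative metrics.

Metrics mirror standard segmentation evaluation for this task: a pooled
row-normalized confusion matrix over all voxels of all patients (rows =
true class, columns = predicted class, fixed air/soft/bone order), and
per-class mean absolute HU error where predicted labels are mapped to
their representative HU values (-1000/0/500) and compared against the
original continuous HU of the ground truth, grouped by true class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import extract_patch, slice_x_mm_of_index
from .tissue import DEFAULT_SCHEME, TissueScheme, labels_to_hu_array, segment_hu_array
from .volumes import HUVolume, LabelVolume


@dataclass
class ConfusionMatrix3:
    counts: np.ndarray            # 3x3 int, rows = true, cols = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 3x3 matrix")

    @property
    def row_normalized(self) -> np.ndarray:
        """Row-normalized matrix; rows with zero support are NaN (flagged
        by :attr:`undefined_rows`, never silently divided)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        return np.divide(self.counts, sums, out=np.full((3, 3), np.nan),
                         where=sums > 0)

    @property
    def undefined_rows(self) -> list:
        return [c for c in range(3) if self.counts[c].sum() == 0]

    def recall(self) -> np.ndarray:
        return np.diag(self.row_normalized)

    def precision(self) -> np.ndarray:
        sums = self.counts.sum(axis=0)
        return np.divide(np.diag(self.counts), sums,
                         out=np.full(3, np.nan), where=sums > 0)

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)


@dataclass
class MAEReport:
    """Per-class and overall MAE in HU, aggregated as mean +/- SD across
    patients.  ``per_class_mae[c]`` is NaN when no patient has class c."""

    per_class_mae: np.ndarray       # (3,) HU
    per_class_sd: np.ndarray        # (3,) HU
    overall_mae: float
    overall_sd: float
    n_patients: int


def confusion_matrix(pred, true) -> ConfusionMatrix3:
    """Pooled 3x3 confusion counts over one or more aligned volume pairs."""
    if isinstance(pred, (LabelVolume, np.ndarray)):
        pred, true = [pred], [true]
    counts = np.zeros((3, 3), dtype=np.int64)
    for p, t in zip(pred, true, strict=True):
        pa = p.values if isinstance(p, LabelVolume) else np.asarray(p)
        ta = t.values if isinstance(t, LabelVolume) else np.asarray(t)
        if pa.shape != ta.shape:
            raise ValueError("prediction and truth shapes differ")
        idx = ta.astype(np.int64).ravel() * 3 + pa.astype(np.int64).ravel()
        counts += np.bincount(idx, minlength=9).reshape(3, 3)
    return ConfusionMatrix3(counts)


def class_mae_single(pred: LabelVolume, true_hu: HUVolume,
                     scheme: TissueScheme = DEFAULT_SCHEME):
    """One patient: (per-class MAE over voxels whose TRUE class is c,
    overall MAE).  Empty classes give NaN."""
    if pred.values.shape != true_hu.values.shape:
        raise ValueError("prediction and truth shapes differ")
    pred_hu = labels_to_hu_array(pred.values, scheme)
    err = np.abs(pred_hu - true_hu.values)
    true_labels = segment_hu_array(true_hu.values, scheme)
    per_class = np.full(3, np.nan)
    for c in range(3):
        mask = true_labels == c
        if mask.any():
            per_class[c] = err[mask].mean()
    return per_class, float(err.mean())


def class_mae(preds, true_hus, scheme: TissueScheme = DEFAULT_SCHEME) -> MAEReport:
    """Aggregate per-patient MAE values as mean +/- SD across patients."""
    if isinstance(preds, LabelVolume):
        preds, true_hus = [preds], [true_hus]
    per_class_rows, overall_rows = [], []
    for p, t in zip(preds, true_hus, strict=True):
        pc, ov = class_mae_single(p, t, scheme)
        per_class_rows.append(pc)
        overall_rows.append(ov)
    pc = np.asarray(per_class_rows)
    ov = np.asarray(overall_rows)
    with np.errstate(invalid="ignore"):
        return MAEReport(
            per_class_mae=np.nanmean(pc, axis=0),
            per_class_sd=np.nanstd(pc, axis=0),
            overall_mae=float(ov.mean()),
            overall_sd=float(ov.std()),
            n_patients=len(overall_rows),
        )


def reconstruct_volume(model, projections, slice_positions_mm,
                       template: LabelVolume) -> LabelVolume:
    """Predict each requested sagittal slice and stack along the lateral
    axis.  ``template`` supplies the output grid (spacing/origin and the
    vertical x depth slice shape at native resolution)."""
    from .tissue import probs_to_labels

    ny, nz = template.values.shape[1], template.values.shape[2]
    planes = []
    for x_mm in slice_positions_mm:
        patch = extract_patch(projections, x_mm)
        pred = model.predict_slice(patch.values)
        labels = probs_to_labels(pred.probs)
        planes.append(_resize_nearest(labels, (ny, nz)))
    out = np.stack(planes, axis=0)
    return LabelVolume(out, template.voxel_size_mm, template.origin_mm)


def _resize_nearest(plane: np.ndarray, out_shape) -> np.ndarray:
    iy = (np.arange(out_shape[0]) * plane.shape[0]) // out_shape[0]
    iz = (np.arange(out_shape[1]) * plane.shape[1]) // out_shape[1]
    return plane[np.ix_(iy, iz)]


def coronal_plane(assembled: LabelVolume, depth_index: int) -> np.ndarray:
    """(lateral x vertical) coronal plane of a reassembled volume."""
    return assembled.values[:, :, depth_index].copy()


def evaluate(model, patients, out_shape, train_ids=()):
    """Evaluate on held-out patients.

    ``patients`` is a list of dicts with keys ``patient_id``, ``projections``
    (ProjectionSet), ``labels`` (LabelVolume truth), ``hu`` (HUVolume truth)
    and ``slice_indices`` (which sagittal planes to predict).  Raises if any
    patient also appears in ``train_ids`` (split contamination).
    Returns a report dict with the pooled confusion matrix, MAE report,
    per-class recall/precision and per-patient predictions.
    """
    from .tissue import probs_to_labels

    contaminated = {p["patient_id"] for p in patients} & set(train_ids)
    if contaminated:
        raise ValueError(f"patients {sorted(contaminated)} appear in the training split")
    preds_slices, true_slices = [], []
    preds_vols, true_hu_crops = [], []
    cm = ConfusionMatrix3(np.zeros((3, 3), dtype=np.int64))
    for pat in patients:
        labels, hu = pat["labels"], pat["hu"]
        pred_planes, true_planes, hu_planes = [], [], []
        for idx in pat["slice_indices"]:
            x_mm = slice_x_mm_of_index(labels, idx)
            patch = extract_patch(pat["projections"], x_mm)
            pred = probs_to_labels(model.predict_slice(patch.values).probs)
            from .dataset import target_slice
            truth = target_slice(labels, idx, out_shape)
            hu_plane = _resize_nearest_f(hu.values[idx], out_shape)
            pred_planes.append(pred)
            true_planes.append(truth)
            hu_planes.append(hu_plane)
        pred_vol = np.stack(pred_planes)
        true_vol = np.stack(true_planes)
        cm = cm + confusion_matrix(pred_vol, true_vol)
        preds_slices.append(pred_vol)
        true_slices.append(true_vol)
        preds_vols.append(LabelVolume(pred_vol, labels.voxel_size_mm, labels.origin_mm))
        true_hu_crops.append(HUVolume(np.stack(hu_planes), hu.voxel_size_mm, hu.origin_mm))
    mae = class_mae(preds_vols, true_hu_crops)
    return {
        "confusion": cm,
        "mae": mae,
        "recall": cm.recall(),
        "precision": cm.precision(),
        "accuracy": cm.accuracy(),
        "n_patients": len(patients),
        "predictions": preds_slices,
        "truths": true_slices,
    }


def _resize_nearest_f(plane: np.ndarray, out_shape) -> np.ndarray:
    iy = (np.arange(out_shape[0]) * plane.shape[0]) // out_shape[0]
    iz = (np.arange(out_shape[1]) * plane.shape[1]) // out_shape[1]
    return plane[np.ix_(iy, iz)]


def save_montage(planes, path, n_cols: int = 4) -> None:
    """Greyscale montage preview (PNG) of label planes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(planes)
    n_rows = -(-n // n_cols)
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(2.2 * n_cols, 2.2 * n_rows))
    axes = np.atleast_1d(axes).ravel()
    for ax in axes:
        ax.axis("off")
    for ax, plane in zip(axes, planes):
        ax.imshow(np.asarray(plane).T, origin="lower", cmap="gray", vmin=0, vmax=2)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
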