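"""Desk-scale end-to-end pipeline: phantoms -> projections -> patches ->
training -> held-out evaluation, all from one seed.

This is the package's self-contained study surrogate: a cohort of
randomized chest phantoms replaces the patient CT archive, the physics
simulator replaces the tomosynthesis system, and the slice-wise model is
trained and scored exactly as the full-scale pipeline would be.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import SplitSpec, build_samples, split_patients
from .evaluation import ConfusionMatrix3, MAEReport, class_mae, confusion_matrix
from .model import SliceSegmenter, build_model
from .phantom import make_phantom, sample_spec
from .presets import RunConfig, desk_run_config
from .training import TrainConfig, train
from .volumes import HUVolume, LabelVolume, derive_seed


@dataclass
class DeskDataset:
    inputs: np.ndarray            # (N, views, rows, width)
    targets: np.ndarray           # (N, rows_out, depth_out) labels
    hu_planes: np.ndarray         # (N, rows_out, depth_out) true continuous HU
    patient_ids: list
    config: RunConfig


@dataclass
class DeskResult:
    accuracy: float
    recall: np.ndarray
    precision: np.ndarray
    confusion: ConfusionMatrix3
    mae: MAEReport
    history: list
    n_train: int
    n_test_patients: int
    model: SliceSegmenter
    predictions: list = None        # per test patient, stacked pred planes


def _resize_nearest(plane: np.ndarray, out_shape) -> np.ndarray:
    iy = (np.arange(out_shape[0]) * plane.shape[0]) // out_shape[0]
    iz = (np.arange(out_shape[1]) * plane.shape[1]) // out_shape[1]
    return plane[np.ix_(iy, iz)]


def generate_desk_dataset(cfg: RunConfig) -> DeskDataset:
    """Simulate the full desk cohort: one randomized phantom per patient,
    physics-augmented projections, and aligned patch/target/HU triples."""
    base = derive_seed(cfg.seed, "phantom")
    specs = [sample_spec((base + i) % 2**31, cfg.grid_shape, cfg.voxel_size_mm)
             for i in range(cfg.n_phantoms)]
    samples, _ = build_samples(specs, cfg.geometry, cfg.physics,
                               out_shape=cfg.out_shape,
                               slices_per_patient=cfg.slices_per_patient)
    # continuous-HU target planes for the MAE metric
    hu_planes = {}
    for spec in specs:
        hu, _ = make_phantom(spec)
        hu_planes[f"P{spec.seed:05d}"] = hu
    inputs = np.stack([s.input.values for s in samples]).astype(np.float32)
    targets = np.stack([s.target for s in samples]).astype(np.uint8)
    hp = np.stack([
        _resize_nearest(hu_planes[s.patient_id].values[s.slice_index], cfg.out_shape)
        for s in samples])
    pids = [s.patient_id for s in samples]
    return DeskDataset(inputs, targets, hp, pids, cfg)


def split_desk(data: DeskDataset):
    """Patient-level split using the study's train/val/test proportions."""
    unique = sorted(set(data.patient_ids))
    train_ids, val_ids, test_ids = split_patients(
        unique, SplitSpec(seed=data.config.seed))
    pid = np.array(data.patient_ids)
    masks = {name: np.isin(pid, list(ids))
             for name, ids in (("train", train_ids), ("val", val_ids), ("test", test_ids))}
    assert not (set(train_ids) & set(test_ids))
    return masks, (train_ids, val_ids, test_ids)


def train_desk_model(data: DeskDataset, masks, train_cfg: TrainConfig,
                     model_seed: int = 0):
    model = build_model(data.config.model, seed=model_seed)
    tr, va = masks["train"], masks["val"]
    model, history = train(
        model,
        (data.inputs[tr].astype(np.float64), data.targets[tr]),
        train_cfg,
        val_data=(data.inputs[va].astype(np.float64), data.targets[va]))
    return model, history


def evaluate_desk(model: SliceSegmenter, data: DeskDataset, masks) -> DeskResult:
    """Held-out metrics: pooled confusion/recall/accuracy over test voxels
    and per-patient MAE against the continuous-HU truth."""
    te = masks["test"]
    idx = np.nonzero(te)[0]
    if idx.size == 0:
        raise ValueError("no held-out test patients: cohort too small for the "
                         "configured split fractions")
    preds = []
    for i in idx:
        pred = model.predict_slice(data.inputs[i].astype(np.float64))
        preds.append(np.argmax(pred.probs, axis=-1).astype(np.uint8))
    preds = np.stack(preds)
    truths = data.targets[idx]
    cm = confusion_matrix(preds, truths)
    # MAE grouped per patient
    test_pids = [data.patient_ids[i] for i in idx]
    vox = data.config.voxel_size_mm
    pred_vols, hu_vols = [], []
    for pid in sorted(set(test_pids)):
        rows = [k for k, p in enumerate(test_pids) if p == pid]
        pred_vols.append(LabelVolume(preds[rows], vox))
        hu_vols.append(HUVolume(data.hu_planes[idx[rows]], vox))
    mae = class_mae(pred_vols, hu_vols)
    return DeskResult(
        accuracy=cm.accuracy(), recall=cm.recall(), precision=cm.precision(),
        confusion=cm, mae=mae, history=[], n_train=int(masks["train"].sum()),
        n_test_patients=len(pred_vols), model=model,
        predictions=[v.values for v in pred_vols])


def run_desk_benchmark(seed: int, n_phantoms: int = 200, epochs: int = 20,
                       data: DeskDataset | None = None) -> DeskResult:
    """The full desk pipeline for one seed.  Pass a pre-generated ``data``
    to rerun training/evaluation (e.g., across model seeds) without
    re-simulating the cohort."""
    cfg = desk_run_config(seed=seed, n_phantoms=n_phantoms, epochs=epochs)
    if data is None:
        data = generate_desk_dataset(cfg)
    masks, _ = split_desk(data)
    tcfg = replace(cfg.train, seed=seed)
    model, history = train_desk_model(data, masks, tcfg, model_seed=seed)
    result = evaluate_desk(model, data, masks)
    result.history = history
    return result


def overfit_probe(seed: int = 0, epochs: int = 200, learning_rate: float = 5e-3,
                  max_restarts: int = 3) -> float:
    """Capacity check: memorize two training pairs; returns the best final
    composite training loss.

    Uses a larger step than the study default because the probe is a
    200-step memorization, not a generalization run, and restarts from a
    fresh seeded initialization if the loss plateaus — at this tiny scale
    an occasional initialization traps a channel in a dead-ReLU state,
    which says nothing about model capacity."""
    from .training import composite_loss, one_hot

    cfg = desk_run_config(seed=seed, n_phantoms=2, epochs=epochs)
    cfg.slices_per_patient = 1
    data = generate_desk_dataset(cfg)
    X = data.inputs.astype(np.float64)
    best = np.inf
    for restart in range(max_restarts):
        mseed = derive_seed(seed, "train") + restart
        model = build_model(cfg.model, seed=mseed)
        tcfg = TrainConfig(learning_rate=learning_rate, batch_size=2,
                           epochs=epochs, seed=mseed)
        model, _ = train(model, (X, data.targets), tcfg)
        loss = float(composite_loss(model.forward(X), one_hot(data.targets)))
        best = min(best, loss)
        if best < 0.02:
            break
    return best
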