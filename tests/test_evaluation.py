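"""Confusion matrix, MAE, reassembly and the evaluation driver."""

import numpy as np
import pytest

from oracles import hand_confusion
from tomosynth.evaluation import (ConfusionMatrix3, class_mae, class_mae_single,
                                  confusion_matrix, coronal_plane, evaluate,
                                  reconstruct_volume)
from tomosynth.tissue import labels_to_hu_array, segment_hu_array
from tomosynth.volumes import HUVolume, LabelVolume


class TestConfusionMatrix:
    def test_perfect_prediction_gives_identity(self, rng):
        v = rng.integers(0, 3, (6, 6, 6)).astype(np.uint8)
        cm = confusion_matrix(v, v)
        assert np.allclose(cm.row_normalized, np.eye(3))

    def test_rows_sum_to_one(self, rng):
        t = rng.integers(0, 3, (8, 8, 8))
        p = rng.integers(0, 3, (8, 8, 8))
        cm = confusion_matrix(p, t)
        assert np.allclose(cm.row_normalized.sum(axis=1), 1.0, atol=1e-12)

    def test_six_voxel_hand_example(self):
        true = np.array([0, 0, 1, 1, 2, 2]).reshape(1, 2, 3)
        pred = np.array([0, 1, 1, 1, 2, 1]).reshape(1, 2, 3)
        cm = confusion_matrix(pred, true)
        want = np.array([[0.5, 0.5, 0.0], [0.0, 1.0, 0.0], [0.0, 0.5, 0.5]])
        assert np.allclose(cm.row_normalized, want)

    def test_matches_flat_loop_oracle(self, rng):
        t = rng.integers(0, 3, (5, 7, 4))
        p = rng.integers(0, 3, (5, 7, 4))
        cm = confusion_matrix(p, t)
        assert np.array_equal(cm.counts, hand_confusion(t, p))

    def test_pooled_counts_equal_sum_of_per_patient_counts(self, rng):
        ts = [rng.integers(0, 3, (4, 4, 4)) for _ in range(3)]
        ps = [rng.integers(0, 3, (4, 4, 4)) for _ in range(3)]
        pooled = confusion_matrix(ps, ts)
        summed = sum((confusion_matrix(p, t) for p, t in zip(ps, ts)),
                     ConfusionMatrix3(np.zeros((3, 3), dtype=int)))
        assert np.array_equal(pooled.counts, summed.counts)

    def test_zero_support_row_flagged_not_divided(self):
        true = np.zeros((2, 2, 2), dtype=np.uint8)       # air only
        pred = np.zeros((2, 2, 2), dtype=np.uint8)
        cm = confusion_matrix(pred, true)
        assert cm.undefined_rows == [1, 2]
        assert np.isnan(cm.row_normalized[1]).all()

    def test_recall_off_diagonal_consistency(self, rng):
        t = rng.integers(0, 3, (6, 6, 6))
        p = rng.integers(0, 3, (6, 6, 6))
        cm = confusion_matrix(p, t)
        for c in range(3):
            mask = t == c
            want = (p[mask] == c).mean()
            assert cm.recall()[c] == pytest.approx(want, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


class TestClassMAE:
    def test_perfect_on_representative_truth_is_zero(self, rng):
        labels = rng.integers(0, 3, (5, 5, 5)).astype(np.uint8)
        truth = HUVolume(labels_to_hu_array(labels), 1.0)
        pc, overall = class_mae_single(LabelVolume(labels, 1.0), truth)
        assert overall == 0.0 and np.all(pc == 0.0)

    def test_single_air_voxel_against_minus_850(self):
        truth = HUVolume(np.full((1, 1, 1), -850.0), 1.0)
        pred = LabelVolume(np.zeros((1, 1, 1), dtype=np.uint8), 1.0)
        pc, overall = class_mae_single(pred, truth)
        assert pc[0] == pytest.approx(150.0)
        assert overall == pytest.approx(150.0)

    def test_all_soft_prediction_on_all_air_truth(self):
        truth = HUVolume(np.full((3, 3, 3), -1000.0), 1.0)
        pred = LabelVolume(np.ones((3, 3, 3), dtype=np.uint8), 1.0)
        _, overall = class_mae_single(pred, truth)
        assert overall == pytest.approx(1000.0)

    def test_empty_class_reported_absent(self):
        truth = HUVolume(np.full((2, 2, 2), 40.0), 1.0)    # soft only
        pred = LabelVolume(np.ones((2, 2, 2), dtype=np.uint8), 1.0)
        pc, _ = class_mae_single(pred, truth)
        assert np.isnan(pc[0]) and np.isnan(pc[2]) and pc[1] == pytest.approx(40.0)

    def test_aggregation_across_patients(self, rng):
        preds, truths, overalls = [], [], []
        for s in range(3):
            r = np.random.default_rng(s)
            labels = r.integers(0, 3, (4, 4, 4)).astype(np.uint8)
            hu = labels_to_hu_array(labels) + r.normal(0, 30, labels.shape)
            hu = np.maximum(hu, -1024)
            preds.append(LabelVolume(labels, 1.0))
            truths.append(HUVolume(hu, 1.0))
            overalls.append(np.abs(labels_to_hu_array(labels) - hu).mean())
        rep = class_mae(preds, truths)
        assert rep.n_patients == 3
        assert rep.overall_mae == pytest.approx(np.mean(overalls))
        assert rep.overall_sd == pytest.approx(np.std(overalls))


class _OracleModel:
    """Perfect 'model' that reads the truth it was given."""

    def __init__(self, truth_by_x):
        self.truth_by_x = truth_by_x
        self.calls = 0

    def predict_slice(self, patch_values):
        from tomosynth.model import SlicePrediction
        plane = list(self.truth_by_x.values())[self.calls % len(self.truth_by_x)]
        self.calls += 1
        return SlicePrediction(np.eye(3)[plane])


class TestReassembly:
    def _projections(self):
        from tomosynth.geometry import AcquisitionGeometry
        from tomosynth.projector import ProjectionSet
        geom = AcquisitionGeometry(n_views=3, detector_shape=(32, 32),
                                   detector_pitch_mm=4.0, patient_offset_mm=150.0,
                                   strip_width_px=5)
        return ProjectionSet(np.zeros((3, 32, 32)), "line_integral", geom)

    def test_lateral_extent_and_determinism_and_coronal_gather(self, rng):
        pset = self._projections()
        template = LabelVolume(rng.integers(0, 3, (4, 8, 8)).astype(np.uint8), 3.0)
        truth = {i: template.values[i] for i in range(4)}
        model = _OracleModel(truth)
        xs = [-6.0, -2.0, 2.0, 6.0]
        vol1 = reconstruct_volume(model, pset, xs, template)
        model.calls = 0
        vol2 = reconstruct_volume(model, pset, xs, template)
        assert vol1.values.shape[0] == len(xs)
        assert np.array_equal(vol1.values, vol2.values)
        # coronal plane equals gathering one depth column from each slice
        k = 3
        want = np.stack([truth[i][:, k] for i in range(4)])
        assert np.array_equal(coronal_plane(vol1, k), want)


class TestEvaluateDriver:
    def _patients(self, rng, n=2):
        from tomosynth.geometry import AcquisitionGeometry
        from tomosynth.phantom import PhantomSpec, make_phantom
        from tomosynth.projector import PhysicsConfig, simulate_projections
        geom = AcquisitionGeometry(n_views=4, detector_shape=(64, 64),
                                   detector_pitch_mm=2.5, patient_offset_mm=150.0,
                                   strip_width_px=5)
        patients = []
        for s in range(n):
            spec = PhantomSpec(grid_shape=(24, 24, 24), voxel_size_mm=5.0, seed=s,
                               body_halfaxes_mm=(44.0, 50.0, 40.0),
                               lung_halfaxes_mm=(15.0, 28.0, 22.0),
                               lung_offsets_mm=((-20.0, 2.0, 3.0), (20.0, 2.0, 3.0)),
                               spine_radius_mm=6.0, n_ribs=2)
            hu, labels = make_phantom(spec)
            pset = simulate_projections(hu, geom, PhysicsConfig.ideal())
            patients.append({"patient_id": f"T{s}", "projections": pset,
                             "labels": labels, "hu": hu,
                             "slice_indices": [10, 12, 14]})
        return patients

    def test_truth_reading_oracle_model_gives_identity_confusion(self, rng):
        patients = self._patients(rng)

        class TruthModel:
            def __init__(self):
                self.queue = []

            def predict_slice(self, patch_values):
                from tomosynth.model import SlicePrediction
                return SlicePrediction(np.eye(3)[self.queue.pop(0)])

        model = TruthModel()
        from tomosynth.dataset import target_slice
        for pat in patients:
            for idx in pat["slice_indices"]:
                model.queue.append(target_slice(pat["labels"], idx, (24, 24)))
        report = evaluate(model, patients, out_shape=(24, 24))
        assert np.allclose(np.nan_to_num(report["confusion"].row_normalized),
                           np.eye(3) * ~np.isnan(report["confusion"].row_normalized[:, 0, None]))
        assert report["accuracy"] == 1.0

    def test_majority_class_baseline_gives_constant_column(self, rng):
        patients = self._patients(rng, n=1)

        class AirModel:
            def predict_slice(self, patch_values):
                from tomosynth.model import SlicePrediction
                probs = np.zeros((24, 24, 3))
                probs[..., 0] = 1.0
                return SlicePrediction(probs)

        report = evaluate(AirModel(), patients, out_shape=(24, 24))
        norm = report["confusion"].row_normalized
        present = ~np.isnan(norm[:, 0])
        assert np.allclose(norm[present, 0], 1.0)

    def test_split_contamination_is_hard_error(self, rng):
        patients = self._patients(rng, n=1)
        with pytest.raises(ValueError, match="training split"):
            evaluate(None, patients, out_shape=(24, 24), train_ids={"T0"})
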