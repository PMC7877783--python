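"""Threshold training, the PCA report, voxel classification, and margin
projection."""

import numpy as np
import pytest

from octmargin import classify as cl
from octmargin import phantom as ph
from octmargin import report as rp
from octmargin import texture as tx


def roi(label, rsd, slope):
    return tx.ROIFeatures(mean_intensity=0, intensity_sd=0, mean_waviness=0,
                          mean_roughness_sd=rsd, max_roughness_sd=rsd,
                          mean_slope=slope, slope_sd=0, intensity_entropy=0,
                          local_contrast=0, label=label)


class TestTrain:
    def test_midpoint_threshold(self):
        feats = [roi("tumor", v, 0.0) for v in (4, 5, 6)] \
            + [roi("benign", v, 0.0) for v in (1, 2, 3)]
        model = cl.train(feats)
        assert model.roughness_threshold == pytest.approx(3.5)

    def test_perfect_separation_zero_training_error(self):
        feats = [roi("tumor", 5, 0.1), roi("tumor", 6, 0.1),
                 roi("benign", 1, 0.05), roi("benign", 2, 0.06),
                 roi("adipose", 2, 0.9), roi("adipose", 3, 0.8)]
        model = cl.train(feats)
        assert all(model.predict_roi(f) == f.label for f in feats)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cl.train([roi("tumor", 1, 1), roi("tumor", 2, 2)])

    def test_degenerate_feature_named_in_error(self):
        feats = [roi("tumor", 3.0, 0.1), roi("benign", 3.0, 0.1)]
        with pytest.raises(ValueError, match="mean_roughness_sd"):
            cl.train(feats)

    def test_held_out_accuracy_on_phantom_rois(self, shared_model):
        feats = []
        for pat in ("uniform_tumor", "adipose_only", "infiltrating_boundary"):
            for s in (31, 32):
                p = ph.generate_phantom(ph.PhantomSpec(layout_pattern=pat, seed=s))
                feats += rp.training_rois_from_phantom(p, rois_per_class=5,
                                                       depths=(6, 30))
        by_label = {}
        for f in feats:
            by_label.setdefault(f.label, []).append(f)
        accs = []
        for label, fs in by_label.items():
            preds = [shared_model.predict_roi(f, depth=6) for f in fs]
            accs.append(np.mean([p == label for p in preds]))
        assert np.mean(accs) >= 0.9


class TestPcaReport:
    def test_rank_one_table(self, rng):
        x = rng.standard_normal(100)
        table = np.stack([a * x + b for a, b in
                          zip(rng.uniform(1, 3, 9), rng.uniform(-1, 1, 9))],
                         axis=1)
        report = cl.pca_report(table)
        assert report.explained_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_iid_noise_spreads_variance(self, rng):
        report = cl.pca_report(rng.standard_normal((500, 9)))
        assert np.all(np.abs(report.explained_variance - 1 / 9) < 0.05)

    def test_stair_properties(self, rng):
        report = cl.pca_report(rng.standard_normal((60, 9)))
        assert report.explained_variance.sum() == pytest.approx(1.0)
        assert np.all(np.diff(report.cumulative) >= -1e-12)
        assert report.cumulative[-1] == pytest.approx(1.0)
        assert report.cumulative[4] > report.cumulative[1]

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        table = rng.standard_normal((50, 9))
        table[:, 3] = 2.0
        with pytest.warns(UserWarning):
            report = cl.pca_report(table)
        assert len(report.feature_names) == 8

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            cl.pca_report(np.zeros((1, 9)))

    def test_phantom_roi_table_stair(self, shared_model, default_phantoms):
        feats = rp.training_rois_from_phantom(
            default_phantoms["infiltrating_boundary"], rois_per_class=8,
            depths=(6, 30, 60))
        table = np.stack([f.vector() for f in feats])
        report = cl.pca_report(table)
        assert report.cumulative[min(4, len(report.cumulative) - 1)] \
            > report.cumulative[1]


class TestClassifyVoxels:
    def test_uniform_tumor_foreground(self, shared_model, default_phantoms):
        p = default_phantoms["uniform_tumor"]
        mask, _, _ = rp.segment_foreground(p.oct)
        _, comp = tx.depth_compensate(p.oct, mask)
        labels = cl.classify_voxels(comp, shared_model, mask)
        assert (labels[mask] == ph.TUMOR).mean() >= 0.95

    def test_background_outside_mask(self, shared_model, default_phantoms):
        p = default_phantoms["adipose_only"]
        mask, _, _ = rp.segment_foreground(p.oct)
        _, comp = tx.depth_compensate(p.oct, mask)
        labels = cl.classify_voxels(comp, shared_model, mask)
        assert (labels[~mask] == ph.BACKGROUND).all()

    def test_deterministic(self, shared_model, small_phantom):
        mask, _, _ = rp.segment_foreground(small_phantom.oct)
        _, comp = tx.depth_compensate(small_phantom.oct, mask)
        a = cl.classify_voxels(comp, shared_model, mask)
        b = cl.classify_voxels(comp, shared_model, mask)
        assert np.array_equal(a, b)

    def test_lobule_false_positive_mode(self, shared_model, default_phantoms):
        # normal lobules scatter like tumor: the classifier flags part of
        # the (ground-truth benign) lobule as tumor
        p = default_phantoms["lobule_insert"]
        mask, _, _ = rp.segment_foreground(p.oct)
        _, comp = tx.depth_compensate(p.oct, mask)
        labels = cl.classify_voxels(comp, shared_model, mask)
        benign_voxels = (p.labels == ph.BENIGN) & mask
        fp_fraction = (labels[benign_voxels] == ph.TUMOR).mean()
        assert fp_fraction > 0.01

    def test_shape_mismatch_rejected(self, shared_model):
        with pytest.raises(ValueError):
            cl.classify_voxels(np.zeros((4, 8, 8)), shared_model,
                               np.zeros((4, 8, 9), bool))


class TestProjectMargin:
    def test_no_tumor_empty_mask(self):
        labels = np.full((20, 16, 16), ph.BENIGN, np.uint8)
        m = cl.project_margin(labels, np.zeros((16, 16), int))
        assert not m.mask.any()

    def test_depth_window_controls_detection(self):
        # tumor slab at 0.5 mm depth (z=100): visible at 1.0 mm
        # projection, invisible at 0.3 mm
        nz = 220
        labels = np.full((nz, 32, 32), ph.BENIGN, np.uint8)
        labels[100:140, 8:24, 8:24] = ph.TUMOR
        top = np.zeros((32, 32), int)
        deep = cl.project_margin(labels, top, depth_mm=1.0,
                                 min_area_mm2=0.01)
        shallow = cl.project_margin(labels, top, depth_mm=0.3,
                                    min_area_mm2=0.01)
        assert deep.mask[8:24, 8:24].all()
        assert not shallow.mask.any()

    def test_monotone_in_depth(self, shared_model, default_phantoms):
        p = default_phantoms["deep_focus"]
        mask, top, _ = rp.segment_foreground(p.oct)
        _, comp = tx.depth_compensate(p.oct, mask)
        labels = cl.classify_voxels(comp, shared_model, mask)
        areas = [cl.project_margin(labels, top, depth_mm=d).mask.sum()
                 for d in (0.3, 0.6, 1.0)]
        assert areas[0] <= areas[1] <= areas[2]

    def test_small_components_removed(self):
        labels = np.full((10, 32, 32), ph.BENIGN, np.uint8)
        labels[2, 5, 5] = ph.TUMOR  # single-pixel footprint
        m = cl.project_margin(labels, np.zeros((32, 32), int),
                              min_area_mm2=0.01)
        assert not m.mask.any()

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            cl.project_margin(np.zeros((4, 4, 4), np.uint8),
                              np.zeros((4, 4), int), depth_mm=0.0)


class TestSpecimenCall:
    def test_empty_mask_negative(self):
        m = cl.MarginMask(np.zeros((16, 16), bool), 1.0, 0.01, 1e-4)
        assert cl.specimen_call(m) == "negative"

    def test_area_threshold(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = True  # one 10x10 um pixel = 1e-4 mm^2
        m = cl.MarginMask(mask, 1.0, 0.01, 1e-4)
        assert cl.specimen_call(m, min_area_mm2=0.01) == "negative"
        mask[:10, :10] = True
        m2 = cl.MarginMask(mask, 1.0, 0.01, 1e-4)
        assert cl.specimen_call(m2, min_area_mm2=0.01) == "positive"
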