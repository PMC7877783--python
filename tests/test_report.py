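"""Specimen-level evaluation, overlays, config round trip, and the
end-to-end pipeline."""

import numpy as np
import pytest
import yaml

from octmargin import classify as cl
from octmargin import report as rp
from octmargin.config import PipelineConfig, load_config


class TestEvaluate:
    def test_study_counts_both_conventions(self):
        calls = ["positive"] * 8 + ["positive"] * 2 + ["negative"] * 10
        truth = ["positive"] * 8 + ["negative"] * 12
        t = rp.evaluate(calls, truth)
        assert (t.tp, t.fp, t.tn, t.fn) == (8, 2, 10, 0)
        assert t.ppv_paper == pytest.approx(1.0)
        assert t.npv_paper == pytest.approx(0.8333, abs=1e-3)
        assert t.ppv_std == pytest.approx(0.8)
        assert t.npv_std == pytest.approx(1.0)

    def test_all_correct(self):
        t = rp.evaluate(["positive", "negative"], ["positive", "negative"])
        for v in (t.ppv_paper, t.npv_paper, t.ppv_std, t.npv_std,
                  t.sensitivity, t.specificity):
            assert v == pytest.approx(1.0)

    def test_hand_computed_contingency(self):
        # TP=3, FP=1, FN=2, TN=4
        calls = ["positive"] * 3 + ["negative"] * 2 + ["positive"] + ["negative"] * 4
        truth = ["positive"] * 5 + ["negative"] * 5
        t = rp.evaluate(calls, truth)
        assert (t.tp, t.fp, t.fn, t.tn) == (3, 1, 2, 4)
        assert t.ppv_std == pytest.approx(0.75)
        assert t.npv_std == pytest.approx(2 / 3, abs=1e-9)
        assert t.sensitivity == pytest.approx(0.6)

    def test_paper_convention_is_sensitivity_specificity(self):
        t = rp.evaluate(["positive", "negative", "positive", "negative"],
                        ["positive", "positive", "negative", "negative"])
        assert t.ppv_paper == t.sensitivity
        assert t.npv_paper == t.specificity

    def test_counts_round_trip_from_fractions(self):
        t = rp.evaluate(["positive"] * 8 + ["negative"] * 12,
                        ["positive"] * 7 + ["negative"] * 13)
        assert round(t.ppv_paper * (t.tp + t.fn)) == t.tp

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rp.evaluate(["positive"], ["positive", "negative"])
        with pytest.raises(ValueError):
            rp.evaluate(["yes"], ["positive"])


class TestOverlay:
    def _mask(self, arr):
        return cl.MarginMask(arr, 1.0, 0.01, 1e-4)

    def test_empty_mask_identity(self, rng):
        photo = rng.random((16, 16, 3))
        out = rp.overlay(photo, self._mask(np.zeros((16, 16), bool)), 0.5)
        assert np.allclose(out[..., :3], photo)
        assert np.allclose(out[..., 3], 1.0)

    def test_full_mask_opaque_red(self, rng):
        photo = rng.random((8, 8, 3))
        out = rp.overlay(photo, self._mask(np.ones((8, 8), bool)), alpha=1.0)
        assert np.allclose(out[..., 0], 1.0)
        assert np.allclose(out[..., 1:3], 0.0)

    def test_tinted_pixels_equal_mask(self, rng):
        photo = np.full((12, 12, 3), 0.5)
        mask = np.zeros((12, 12), bool)
        mask[3:7, 2:9] = True
        out = rp.overlay(photo, self._mask(mask), 0.5)
        changed = ~np.all(np.isclose(out[..., :3], 0.5), axis=-1)
        assert np.array_equal(changed, mask)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            rp.overlay(np.zeros((4, 4, 3)), self._mask(np.zeros((5, 5), bool)))


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig()
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = load_config(path)
        assert back.to_dict() == cfg.to_dict()

    def test_every_default_present_in_document(self):
        doc = PipelineConfig().to_dict()
        for key in ("texture", "projection_depth_mm", "min_component_mm2",
                    "fov_mm", "overlap_fraction", "rois_per_class"):
            assert key in doc


class TestPipeline:
    def test_adipose_specimen_negative(self, shared_model):
        cfg = PipelineConfig(phantom={"layout_pattern": "adipose_only",
                                      "seed": 77, "grid_shape": [64, 64, 220]})
        report = rp.run_pipeline(cfg, model=shared_model)
        assert report.call == "negative"

    def test_uniform_tumor_positive_full_footprint(self, shared_model):
        cfg = PipelineConfig(phantom={"layout_pattern": "uniform_tumor",
                                      "seed": 78, "grid_shape": [64, 64, 220]})
        report = rp.run_pipeline(cfg, model=shared_model)
        assert report.call == "positive"
        assert report.margin.mask.mean() >= 0.99
        assert report.surface_class_fractions["tumor"] > 0.9
        fr = report.surface_class_fractions
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_repeat_runs_identical(self, shared_model):
        cfg = PipelineConfig(phantom={"layout_pattern": "lobule_insert",
                                      "seed": 79, "grid_shape": [64, 64, 220]})
        a = rp.run_pipeline(cfg, model=shared_model)
        b = rp.run_pipeline(cfg, model=shared_model)
        assert a.call == b.call
        assert np.array_equal(a.margin.mask, b.margin.mask)
        assert a.to_dict() == b.to_dict()

    def test_stitching_stage_exercised(self, shared_model):
        # shrink the FOV so the ROI spans several strips
        cfg = PipelineConfig(phantom={"layout_pattern": "infiltrating_boundary",
                                      "seed": 80, "grid_shape": [64, 64, 220]},
                             fov_mm=0.3)
        report = rp.run_pipeline(cfg, model=shared_model)
        assert report.stages["mosaic"]["n_strips"] > 1
        assert report.stages["mosaic"]["stitch_mad"] < 0.05

    def test_artifacts_written(self, tmp_path, shared_model):
        cfg = PipelineConfig(phantom={"layout_pattern": "deep_focus",
                                      "seed": 81, "grid_shape": [64, 64, 220]},
                             out_dir=str(tmp_path))
        report = rp.run_pipeline(cfg, model=shared_model, specimen_id="sp0")
        out = tmp_path / "sp0"
        for name in ("labels.ome.tif", "margin_mask.png", "overlay.png",
                     "margin_components.csv", "surfaces.csv", "report.json",
                     "palette.json"):
            assert (out / name).exists(), name

    def test_stage_error_carries_stage_name(self):
        cfg = PipelineConfig(inputs={"oct": "/nonexistent/volume.tif"})
        with pytest.raises(RuntimeError, match="pipeline"):
            rp.run_pipeline(cfg)
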