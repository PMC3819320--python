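import json

import numpy as np
import pytest

import pibquant as pq
from pibquant.phantom import (
    PhantomConfig,
    build_geometry,
    build_phantom,
    build_testretest_cohort,
    perturb_segmentation,
)


class TestGeometryAndDeterminism:
    def test_same_seed_gives_bit_identical_volumes(self):
        cfg = PhantomConfig(noise_sd=0.5, seed=123)
        img1, vol1, _ = build_phantom(cfg)
        img2, vol2, _ = build_phantom(cfg)
        np.testing.assert_array_equal(img1.voxels, img2.voxels)
        np.testing.assert_array_equal(vol1.labels, vol2.labels)

    def test_all_regions_at_least_27_voxels(self, default_phantom):
        _, _, truth = default_phantom
        assert min(truth.volumes.values()) >= 27

    def test_reference_region_has_zero_true_binding(self, default_phantom):
        _, _, truth = default_phantom
        assert truth.kinetics["Cerebellum-Cortex"].bp_nd_true == 0.0

    def test_every_label_named_and_bilateral_structures_split(self):
        vol = build_geometry()
        present = {vol.lut[i] for i in vol.present_ids()}
        assert "ctx-lh-precuneus" in present and "ctx-rh-precuneus" in present
        assert "Left-Cerebellum-Cortex" in present and "Right-Cerebellum-Cortex" in present
        assert "Brain-Stem" in present and "CSF" in present

    def test_truth_json_is_loadable(self, default_phantom, tmp_path):
        _, _, truth = default_phantom
        truth.to_json(tmp_path / "truth.json")
        back = json.loads((tmp_path / "truth.json").read_text())
        assert back["mcbp_true"] == pytest.approx(truth.mcbp_true)
        assert back["kinetics"]["ctx-precuneus"]["r1"] == pytest.approx(1.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            PhantomConfig(psf_fwhm_mm=-2.0)


class TestKineticClosure:
    def test_noiseless_pipeline_recovers_every_regional_bp(self, quantified_phantom):
        report, _, _, truth = quantified_phantom
        for name, params in truth.kinetics.items():
            assert report.regional_bp[name] == pytest.approx(
                params.bp_nd_true, abs=0.02
            ), name

    def test_null_phantom_has_no_binding_anywhere(self):
        img, labels, truth = build_phantom(PhantomConfig(binding_scale=0.0))
        assert truth.mcbp_true == 0.0
        report, _, _ = pq.quantify(img, labels)
        for name in truth.kinetics:
            assert abs(report.regional_bp[name]) <= 0.01
        assert report.pib_status == "negative"

    def test_noise_scales_with_activity_over_duration(self):
        cfg = PhantomConfig(noise_sd=1.0, seed=5)
        img_n, _, _ = build_phantom(cfg)
        img_c, _, _ = build_phantom(PhantomConfig())
        resid = img_n.voxels.astype(float) - img_c.voxels.astype(float)
        # long frames (300 s) must be quieter than short frames (5 s) at similar activity
        thr_e = 0.5 * img_c.voxels[..., 20].max()
        thr_l = 0.5 * img_c.voxels[..., -1].max()
        early = resid[..., 20][img_c.voxels[..., 20] > thr_e]
        late = resid[..., -1][img_c.voxels[..., -1] > thr_l]
        assert late.std() < early.std()


class TestPerturbSegmentation:
    def test_zero_magnitude_is_identity(self, default_phantom):
        _, labels, _ = default_phantom
        out = perturb_segmentation(labels, 0.0, seed=1)
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_deterministic_under_seed(self, default_phantom):
        _, labels, _ = default_phantom
        a = perturb_segmentation(labels, 0.05, seed=42)
        b = perturb_segmentation(labels, 0.05, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_interior_preserved_and_regions_survive(self, default_phantom):
        _, labels, _ = default_phantom
        out = perturb_segmentation(labels, 0.4, seed=3)
        from scipy.ndimage import binary_erosion

        for label_id in labels.present_ids():
            interior = binary_erosion(labels.labels == label_id)
            assert np.all(out.labels[interior] == label_id)
            assert (out.labels == label_id).sum() >= 1

    def test_total_labeled_mass_conserved_within_two_percent(self, default_phantom):
        _, labels, _ = default_phantom
        out = perturb_segmentation(labels, 0.05, seed=9, outline_shift_sd=0.1)
        n0 = (labels.labels != 0).sum()
        n1 = (out.labels != 0).sum()
        assert abs(n1 - n0) / n0 < 0.02

    def test_magnitude_out_of_range_rejected(self, default_phantom):
        _, labels, _ = default_phantom
        with pytest.raises(ValueError, match="magnitude"):
            perturb_segmentation(labels, 0.6, seed=0)

    def test_frozen_compartments_untouched(self, default_phantom):
        _, labels, _ = default_phantom
        out = perturb_segmentation(labels, 0.1, seed=13, outline_shift_sd=0.1)
        for name in ("CSF", "Left-Lateral-Ventricle", "Left-Cerebellum-Cortex"):
            ids = [i for i, n in labels.lut.items() if n == name]
            before = np.isin(labels.labels, ids)
            after = np.isin(out.labels, ids)
            np.testing.assert_array_equal(before, after)


def test_cohort_builder_spans_both_pib_classes():
    subjects, truths = build_testretest_cohort(n_subjects=6, seed=1)
    assert len(subjects) == 6
    statuses = {pq.classify_pib(t.mcbp_true) for t in truths}
    assert statuses == {"positive", "negative"}
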