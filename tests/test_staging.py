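"""Sporulation-stage categorization: segmentation, feature rules, curvature,
stage table and the eigenimage basis."""

import numpy as np
import pytest

from slimspore.staging import (CellSegmentation, NoCellError, SporeFeature,
                               assign_stage, classify_cell,
                               classify_feature_shape, crop_and_align,
                               detect_spore_feature, eigenimage_basis,
                               normalized_spore_coordinate, segment_cell,
                               septum_curvature)


def make_feature(major, minor, mask=None, curvature=None, channel="mYPet"):
    if mask is None:
        mask = np.zeros((8, 8), dtype=bool)
        mask[3:5, 3:5] = True
    return SporeFeature(mask=mask, centroid=(4.0, 4.0), area=int(mask.sum()),
                        major_axis=major, minor_axis=minor, orientation=0.0,
                        summed_intensity=float(mask.sum()), channel=channel,
                        curvature=curvature)


class TestSegmentation:
    def test_recovers_cell_dimensions_within_2px(self, stage_images):
        geom, stacks = stage_images["I"]
        seg = segment_cell(stacks["FM"].frames[0])
        true_len = (geom.length_nm + 2 * geom.radius_nm) / geom.pixel_size_nm
        true_w = 2 * geom.radius_nm / geom.pixel_size_nm
        assert seg.total_length_px == pytest.approx(true_len, abs=2)
        assert seg.width_px == pytest.approx(true_w, abs=2)

    def test_blank_frame_raises(self):
        with pytest.raises(NoCellError):
            segment_cell(np.zeros((32, 32)))

    def test_horizontal_cell_orientation_near_zero(self, stage_images):
        _, stacks = stage_images["I"]
        seg = segment_cell(stacks["FM"].frames[0])
        assert abs(seg.orientation_deg) < 5


class TestFeatureDetection:
    def test_stage_I_mypet_has_no_feature(self, stage_images):
        _, stacks = stage_images["I"]
        seg = segment_cell(stacks["FM"].frames[0])
        assert detect_spore_feature(stacks["mYPet"].frames[0], seg) is None

    def test_stage_II_i_septum_found_noise_free(self, stage_images):
        _, stacks = stage_images["II_i"]
        seg = segment_cell(stacks["FM"].frames[0])
        feat = detect_spore_feature(stacks["mYPet"].frames[0], seg)
        assert feat is not None
        assert feat.area > 10
        assert classify_feature_shape(feat) == "septa"

    def test_small_area_rule_rejects_8px_component(self, config):
        # a synthetic bright blob of < 10 px inside an otherwise dark cell
        img = np.zeros((20, 50))
        rr, cc = np.mgrid[0:20, 0:50]
        cell = np.hypot(np.clip(np.abs(cc - 25) - 18, 0, None), rr - 10) <= 6
        img[cell] = 1.0
        img[9:11, 41:45] = 50.0     # 8 px, near the cell end
        seg = CellSegmentation(mask=cell, center=(10.0, 25.0),
                               orientation_deg=0.0, body_length_px=36,
                               width_px=12, bounding_box=(4, 1, 17, 49))
        assert detect_spore_feature(img, seg) is None

    def test_brightest_candidate_wins(self, config):
        img = np.zeros((20, 60))
        rr, cc = np.mgrid[0:20, 0:60]
        cell = np.hypot(np.clip(np.abs(cc - 30) - 22, 0, None), rr - 10) <= 7
        img[cell] = 1.0
        img[6:13, 48:52] = 40.0     # bright candidate, pole side
        img[6:13, 8:12] = 25.0      # dimmer candidate, other pole
        seg = CellSegmentation(mask=cell, center=(10.0, 30.0),
                               orientation_deg=0.0, body_length_px=44,
                               width_px=14, bounding_box=(3, 1, 18, 59))
        feat = detect_spore_feature(img, seg)
        assert feat is not None
        assert feat.centroid[1] == pytest.approx(49.5, abs=1)


class TestShapeAndCurvature:
    @pytest.mark.parametrize("major,minor,expected", [
        (2.4, 1.0, "septa"),
        (1.0, 1.0, "filled"),
        (1.2, 1.0, "filled"),     # strict inequality at the threshold
        (1.0, 0.0, "septa"),      # degenerate ellipse
    ])
    def test_aspect_ratio_classes(self, major, minor, expected):
        assert classify_feature_shape(make_feature(major, minor)) == expected

    def test_straight_skeleton_curvature_zero(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:16, 9] = True
        f = make_feature(12, 1, mask=mask)
        assert septum_curvature(f) == pytest.approx(0.0, abs=0.05)

    def test_semicircular_skeleton_curvature_two(self):
        mask = np.zeros((64, 64), dtype=bool)
        theta = np.linspace(-np.pi / 2, np.pi / 2, 600)
        r = 20
        rows = np.round(32 + r * np.sin(theta)).astype(int)
        cols = np.round(32 - r * np.cos(theta)).astype(int)
        mask[rows, cols] = True
        f = make_feature(2 * r, r, mask=mask)
        assert septum_curvature(f) == pytest.approx(2.0, abs=0.15)

    @pytest.mark.parametrize("angle_deg", [0, 30, 75, 120])
    def test_curvature_rotation_invariant(self, angle_deg):
        theta = np.linspace(-np.pi / 2, np.pi / 2, 400)
        r = 15
        a = np.radians(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        pts = rot @ np.vstack([r * np.sin(theta), -r * np.cos(theta)])
        mask = np.zeros((72, 72), dtype=bool)
        mask[np.round(36 + pts[0]).astype(int),
             np.round(36 + pts[1]).astype(int)] = True
        f = make_feature(2 * r, r, mask=mask)
        assert septum_curvature(f) == pytest.approx(2.0, abs=0.25)

    def test_tiny_skeleton_curvature_zero(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        assert septum_curvature(make_feature(1, 1, mask=mask)) == 0.0

    def test_rendered_engulfment_dome_curvature_above_one(self, stage_images):
        _, stacks = stage_images["II_iii"]
        res = classify_cell(stacks["mYPet"], stacks["FM"])
        assert res.mypet_feature is not None
        assert res.mypet_feature.curvature > 1.0


class TestStageTable:
    @pytest.mark.parametrize("mypet,fm,expected", [
        (None, None, "I_pre"),
        (None, ("septa", None), "I_pre"),
        (("septa", 0.3), ("septa", None), "II_i"),
        (("filled", None), ("septa", None), "II_ii"),
        (("septa", 1.7), ("septa", None), "II_iii"),
        (("filled", None), ("filled", None), "III"),
        (("septa", 0.3), ("filled", None), "indeterminate"),
        (("septa", 1.0), ("septa", None), "indeterminate"),  # kappa == 1
        (("filled", None), None, "indeterminate"),
    ])
    def test_decision_table(self, mypet, fm, expected):
        def build(desc, channel):
            if desc is None:
                return None
            shape, curv = desc
            f = make_feature(2.0 if shape == "septa" else 1.0, 1.0,
                             curvature=curv, channel=channel)
            f.shape_class = shape
            return f
        assert assign_stage(build(mypet, "mYPet"), build(fm, "FM")) == expected

    def test_pure_function(self):
        f1 = make_feature(2.0, 1.0, curvature=0.2)
        f1.shape_class = "septa"
        f2 = make_feature(2.0, 1.0, curvature=0.2, channel="FM")
        f2.shape_class = "septa"
        assert assign_stage(f1, f2) == assign_stage(f1, f2) == "II_i"


class TestEndToEndClassification:
    @pytest.mark.parametrize("stage,expected", [
        ("I", "I_pre"), ("II_i", "II_i"), ("II_ii", "II_ii"),
        ("II_iii", "II_iii"), ("III", "III"),
    ])
    def test_noise_free_cells_classified_correctly(self, stage_images, stage,
                                                   expected):
        _, stacks = stage_images[stage]
        res = classify_cell(stacks["mYPet"], stacks["FM"])
        assert res.stage == expected


class TestNormalizedCoordinate:
    def setup_method(self):
        self.mask = np.zeros((20, 40), dtype=bool)
        self.mask[8:13, 25:36] = True   # forespore spanning cols 25..35

    def test_extremes_and_midpoint(self):
        assert normalized_spore_coordinate((10, 25), self.mask) == 0.0
        assert normalized_spore_coordinate((10, 35), self.mask) == 1.0
        assert normalized_spore_coordinate((10, 30), self.mask) == \
            pytest.approx(0.5)

    def test_clamped_to_unit_interval(self):
        assert normalized_spore_coordinate((10, 39), self.mask) == 1.0
        assert normalized_spore_coordinate((10, 2), self.mask) == 0.0

    def test_pole_side_left_flips_axis(self):
        assert normalized_spore_coordinate((10, 25), self.mask,
                                           pole_side="left") == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            normalized_spore_coordinate((0, 0), np.zeros((4, 4), dtype=bool))


class TestEigenimages:
    def test_identical_crops_give_rank_one_basis(self, rng):
        v = rng.random((16, 16))
        crops = np.stack([v] * 12) + rng.normal(0, 1e-9, (12, 16, 16))
        basis = eigenimage_basis(crops, n_components=4)
        fracs = basis.eigenvalue_fractions()
        assert fracs[0] > 0.999

    def test_matches_dense_eigendecomposition(self, rng):
        crops = rng.random((30, 16, 16))
        basis = eigenimage_basis(crops, n_components=6)
        X = crops.reshape(30, -1)
        C = X.T @ X / 29
        dense = np.linalg.eigvalsh(C)[::-1]
        np.testing.assert_allclose(basis.eigenvalues, dense[:6], rtol=1e-6,
                                   atol=1e-9)
        # orthonormality of the deflated basis
        V = basis.eigenimages.reshape(6, -1)
        np.testing.assert_allclose(V @ V.T, np.eye(6), atol=1e-6)

    def test_eigenvalues_sorted_descending(self, rng):
        basis = eigenimage_basis(rng.random((20, 16, 16)), n_components=5)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-9)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            eigenimage_basis(rng.random((5, 16, 16)), n_components=257)

    def test_spore_crops_dominated_by_first_component(self, stage_images):
        crops = []
        for stage in ("II_i", "II_ii", "II_iii", "III"):
            _, stacks = stage_images[stage]
            res = classify_cell(stacks["mYPet"], stacks["FM"])
            avg = stacks["mYPet"].frames.mean(axis=0)
            for _ in range(3):   # replicate to have >= 2 crops per class
                crops.append(crop_and_align(avg, res.mypet_feature))
        basis = eigenimage_basis(np.stack(crops), n_components=5)
        fracs = basis.eigenvalue_fractions()
        assert fracs[0] == fracs.max()
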