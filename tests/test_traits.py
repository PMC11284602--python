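import numpy as np
import pytest

from phenoplane.backends import ClassicalBackend, Detection, Mask, OracleBackend
from phenoplane.errors import EmptyMask, LabelMismatch, MarkerNotFound
from phenoplane.fiducial import RectifiedMask
from phenoplane.synthetic_scenes import (
    PartSpec,
    PoseParams,
    SceneSpec,
    render_scene,
    trait_scene,
)
from phenoplane.traits import (
    TRAIT_UNITS,
    TraitMeasurement,
    crown_diameter,
    endpoint_distance,
    leaf_metrics,
    measure_image,
    petiole_length,
    plant_height,
    region_area,
)

from conftest import identity_homography


def tilted_scene(parts, tilt=22.0, azimuth=65.0, scale=30.0, size=(720, 560),
                 anchor=(7.0, 3.0)):
    pose = PoseParams(
        scale_px_per_cm=scale, tilt_deg=tilt, tilt_azimuth_deg=azimuth,
        distance_cm=150.0, plane_anchor_cm=anchor,
        image_anchor_px=(size[0] / 2, size[1] / 2),
    )
    return render_scene(SceneSpec(image_size=size, pose=pose, parts=tuple(parts)))


class TestCrownDiameter:
    def test_identity_calibration_30px_box(self):
        h = identity_homography(0.05)
        det = Detection("crown", (10.0, 10.0, 40.0, 22.0))
        m = crown_diameter(det, h)
        assert m.value == pytest.approx(15.0, abs=1e-9)
        assert m.units == "mm"

    def test_label_mismatch(self):
        with pytest.raises(LabelMismatch):
            crown_diameter(Detection("leaf", (0, 0, 10, 10)), identity_homography())

    def test_zero_width_box_rejected_by_detection_invariant(self):
        with pytest.raises(ValueError):
            Detection("crown", (5, 5, 5, 15))

    def test_recovery_of_14_4_mm_crown_under_projective_pose(self):
        part = PartSpec("crown", "ellipse", (9.0, 2.5), (1.44, 0.58))
        image, gt = tilted_scene([part], tilt=25.0, azimuth=130.0, scale=40.0,
                                 size=(640, 480), anchor=(6.0, 2.5))
        m = measure_image(image, "CD", OracleBackend(gt))[0]
        assert m.value == pytest.approx(14.4, abs=0.15)


class TestEndpointDistances:
    def test_vertical_20cm(self):
        h = identity_homography(1.0)
        bottom = Detection("plant_bottom", (-1.0, -1.0, 1.0, 1.0))
        top = Detection("plant_top", (-1.0, 19.0, 1.0, 21.0))
        assert endpoint_distance(bottom, top, h) == pytest.approx(20.0, abs=1e-9)

    def test_three_four_five(self):
        h = identity_homography(1.0)
        a = Detection("petiole_bottom", (-0.5, -0.5, 0.5, 0.5))
        b = Detection("petiole_top", (2.5, 3.5, 3.5, 4.5))
        assert endpoint_distance(a, b, h) == pytest.approx(5.0, abs=1e-9)

    def test_label_mixup_raises(self):
        h = identity_homography(1.0)
        crown = Detection("crown", (0, 0, 2, 2))
        top = Detection("petiole_top", (0, 8, 2, 10))
        with pytest.raises(LabelMismatch):
            petiole_length(crown, top, h)
        with pytest.raises(LabelMismatch):
            plant_height(crown, top, h)

    def test_recovery_of_24_6_cm_plant_height(self):
        e = 0.9
        parts = [
            PartSpec("plant_bottom", "rect", (8.0, 14.65), (e, e)),
            PartSpec("plant_top", "rect", (8.0, -9.95), (e, e)),
        ]
        image, gt = tilted_scene(parts, tilt=18.0, azimuth=40.0, scale=19.0,
                                 size=(600, 900), anchor=(5.0, 2.35))
        m = measure_image(image, "PH", OracleBackend(gt))[0]
        assert m.value == pytest.approx(24.6, abs=0.25)
        assert m.units == "cm"

    def test_recovery_of_15_1_cm_petiole(self):
        e = 0.9
        parts = [
            PartSpec("petiole_bottom", "rect", (8.0, 9.9), (e, e)),
            PartSpec("petiole_top", "rect", (8.0, -5.2), (e, e)),
        ]
        image, gt = tilted_scene(parts, tilt=24.0, azimuth=290.0, scale=24.0,
                                 size=(600, 760), anchor=(5.0, 2.35))
        m = measure_image(image, "PL", OracleBackend(gt))[0]
        assert m.value == pytest.approx(15.1, abs=0.25)


class TestLeafMetrics:
    def test_axis_aligned_rectangle(self):
        h = identity_homography(0.05)
        bitmap = np.ones((40, 100), dtype=bool)
        la, ll, lw = leaf_metrics(Mask((0, 0, 100, 40), bitmap), h)
        assert la.value == pytest.approx(10.0, rel=0.02)
        assert ll.value == pytest.approx(5.0, rel=0.02)
        assert lw.value == pytest.approx(2.0, rel=0.02)
        assert (la.units, ll.units, lw.units) == ("cm2", "cm", "cm")

    def test_filled_circle(self):
        h = identity_homography(0.05)
        yy, xx = np.mgrid[0:80, 0:80]
        bitmap = (xx - 40.0) ** 2 + (yy - 40.0) ** 2 <= 30.0**2  # r = 1.5 cm
        la, ll, lw = leaf_metrics(Mask((0, 0, 80, 80), bitmap), h)
        assert la.value == pytest.approx(np.pi * 1.5**2, rel=0.02)
        assert ll.value == pytest.approx(3.0, rel=0.02)
        assert lw.value == pytest.approx(3.0, rel=0.02)

    def test_ellipse_leaf_under_projective_pose(self):
        part = PartSpec("leaf", "ellipse", (10.0, 3.0), (7.0, 5.5))
        image, gt = tilted_scene([part], tilt=20.0, azimuth=205.0, scale=34.0,
                                 size=(760, 520), anchor=(7.0, 2.8))
        backend = OracleBackend(gt)
        ll = measure_image(image, "LL", backend)[0]
        lw = measure_image(image, "LW", backend)[0]
        la = measure_image(image, "LA", backend)[0]
        assert ll.value == pytest.approx(7.0, rel=0.01)
        assert lw.value == pytest.approx(5.5, rel=0.01)
        assert la.value == pytest.approx(np.pi * 3.5 * 2.75, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMask):
            leaf_metrics(Mask((0, 0, 8, 8), np.zeros((8, 8), bool)),
                         identity_homography())


class TestRegionArea:
    def test_cell_count_arithmetic(self):
        bitmap = np.zeros((50, 50), dtype=bool)
        bitmap.ravel()[:2000] = True
        rect = RectifiedMask(bitmap, (0.0, 0.0), 0.05)
        assert rect.area_cm2 == pytest.approx(5.0, abs=1e-12)

    def test_region_area_identity(self):
        h = identity_homography(0.05)
        bitmap = np.ones((40, 50), dtype=bool)  # 2000 px
        m = region_area(Mask((0, 0, 50, 40), bitmap), h, "FrA", resolution=0.05)
        assert m.value == pytest.approx(5.0, rel=0.02)

    def test_fruit_blob_of_6_5_cm2(self):
        r = float(np.sqrt(6.5 / np.pi))
        part = PartSpec("fruit", "disk", (9.0, 2.5), (r,))
        image, gt = tilted_scene([part], tilt=15.0, azimuth=10.0, scale=40.0,
                                 size=(640, 480), anchor=(6.0, 2.5))
        m = measure_image(image, "FrA", OracleBackend(gt))[0]
        assert m.value == pytest.approx(6.5, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMask):
            region_area(Mask((0, 0, 4, 4), np.zeros((4, 4), bool)),
                        identity_homography(), "FlA")

    def test_bad_trait_rejected(self):
        with pytest.raises(ValueError):
            region_area(Mask((0, 0, 4, 4), np.ones((4, 4), bool)),
                        identity_homography(), "LA")


class TestMeasureImage:
    def test_cd_scene_oracle_matches_ground_truth(self, rendered_scenes):
        image, gt = rendered_scenes["CD"]
        out = measure_image(image, "CD", OracleBackend(gt), image_id="img0")
        assert len(out) == 1
        assert out[0].value == pytest.approx(gt.truths["CD"], rel=0.01)
        assert out[0].image_id == "img0"
        assert out[0].backend_id == "oracle"

    def test_three_fruits_give_three_measurements(self, rng):
        spec = trait_scene("FrA", rng, n_fruits=3)
        image, gt = render_scene(spec)
        out = measure_image(image, "FrA", OracleBackend(gt))
        assert len(out) == 3
        truths = sorted(p.truth["FrA"] for p in gt.parts)
        assert sorted(m.value for m in out) == pytest.approx(truths, rel=0.02)

    def test_scene_without_marker_raises(self):
        blank = np.full((200, 200, 3), 235, dtype=np.uint8)
        with pytest.raises(MarkerNotFound):
            measure_image(blank, "CD", ClassicalBackend())

    def test_missing_part_returns_empty_list(self, rendered_scenes):
        image, gt = rendered_scenes["CD"]  # no fruit in a crown scene
        assert measure_image(image, "FrA", OracleBackend(gt)) == []
        assert measure_image(image, "FrA", ClassicalBackend()) == []

    def test_unknown_trait_rejected(self, rendered_scenes):
        image, gt = rendered_scenes["CD"]
        with pytest.raises(ValueError):
            measure_image(image, "XX", OracleBackend(gt))


class TestInvariants:
    def test_unit_discipline(self):
        assert TRAIT_UNITS == {
            "CD": "mm", "PH": "cm", "PL": "cm", "LA": "cm2", "LL": "cm",
            "LW": "cm", "FlA": "cm2", "FrA": "cm2",
        }
        with pytest.raises(ValueError):
            TraitMeasurement("CD", 10.0, "cm")
        with pytest.raises(ValueError):
            TraitMeasurement("LA", -1.0, "cm2")

    @pytest.mark.parametrize("seed", [3, 4])
    def test_ll_geq_lw_and_la_bound_for_convex_masks(self, seed):
        gen = np.random.default_rng(seed)
        spec = trait_scene("LA", gen)
        image, gt = render_scene(spec)
        backend = OracleBackend(gt)
        la = measure_image(image, "LA", backend)[0].value
        ll = measure_image(image, "LL", backend)[0].value
        lw = measure_image(image, "LW", backend)[0].value
        assert ll >= lw
        assert la <= ll * lw * 1.001  # convex mask bound

    def test_scaling_monotonicity(self):
        # scaling physical sizes by s scales lengths by s and areas by s^2
        s = 1.3
        values = {}
        for factor in (1.0, s):
            parts = [
                PartSpec("leaf", "ellipse", (10.0, 3.0), (5.0 * factor, 4.0 * factor)),
            ]
            image, gt = tilted_scene(parts, tilt=12.0, azimuth=80.0, scale=30.0,
                                     size=(760, 560), anchor=(7.5, 3.0))
            backend = OracleBackend(gt)
            values[factor] = (
                measure_image(image, "LL", backend)[0].value,
                measure_image(image, "LA", backend)[0].value,
            )
        assert values[s][0] / values[1.0][0] == pytest.approx(s, rel=0.01)
        assert values[s][1] / values[1.0][1] == pytest.approx(s**2, rel=0.02)

    @pytest.mark.parametrize("seed", range(6))
    def test_pose_invariance_oracle_one_percent(self, seed):
        gen = np.random.default_rng(100 + seed)
        trait = ["CD", "PH", "PL", "LA", "FlA", "FrA"][seed % 6]
        spec = trait_scene(trait, gen)
        image, gt = render_scene(spec)
        value = measure_image(image, trait, OracleBackend(gt))[0].value
        assert value == pytest.approx(gt.truths[trait], rel=0.01)
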