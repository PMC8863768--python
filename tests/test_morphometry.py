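"""Morphometric measures: fixed points, boundary conventions, phantom recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import synmorph as sm
from synmorph import morphometry as mm
from synmorph.segmentation import (
    Mask3D, center_of_mass, fill_holes_2d, largest_component, segment_channel,
)

from conftest import NOISE_OFF


@pytest.fixture(scope="module")
def clean_masks(bead_stack_clean):
    nucleus = largest_component(segment_channel(bead_stack_clean, "nucleus"))
    cell = largest_component(fill_holes_2d(segment_channel(bead_stack_clean, "actin")))
    return nucleus, cell


@pytest.fixture(scope="module")
def clean_groove(clean_masks):
    nucleus, _ = clean_masks
    return mm.detect_groove(nucleus)


class TestPolarityIndex:
    B = np.zeros(3)
    A = np.array([0.0, 0.0, 5.0])

    def test_target_at_bead_is_plus_one(self):
        assert mm.polarity_index(self.A, self.B, self.A).index == 1.0

    def test_target_at_cell_centre_is_zero(self):
        assert mm.polarity_index(self.B, self.B, self.A).index == 0.0

    def test_mirrored_target_is_minus_one(self):
        assert mm.polarity_index(-self.A, self.B, self.A).index == -1.0

    def test_lateral_target_projects_to_zero(self):
        assert mm.polarity_index((0, 3, 0), self.B, self.A).index == 0.0

    def test_beyond_bead_clamped(self):
        assert mm.polarity_index((0, 0, 9), self.B, self.A).index == 1.0

    def test_degenerate_axis_raises(self):
        with pytest.raises(mm.DegenerateGeometryError):
            mm.polarity_index(self.A, self.B, self.B)

    def test_planar_mode_ignores_z_offsets(self):
        target = np.array([3.0, 0.0, 5.0])  # at the bead in xy, offset in z
        assert mm.polarity_index(target, self.B, self.A, planar=True).index == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-1, 1), st.floats(0.5, 10))
    def test_index_equals_scalar_projection(self, t, dist):
        """Constructed target at offset t along the axis recovers t exactly."""
        axis = np.array([0.3, -0.4, 0.866])
        axis /= np.linalg.norm(axis)
        res = mm.polarity_index(self.B + t * dist * axis, self.B, self.B + dist * axis)
        assert res.index == pytest.approx(t, abs=1e-9)


class TestClassifyOrientation:
    @pytest.mark.parametrize(
        "angle,category",
        [
            (0.0, "Polarized"),
            (30.0, "Polarized"),
            (45.0, "Polarized"),
            (45.0001, "Central"),
            (90.0, "Central"),
            (135.0, "Central"),
            (135.0001, "Antipolarized"),
            (180.0, "Antipolarized"),
        ],
    )
    def test_boundary_convention(self, angle, category):
        assert mm.classify_orientation(angle) == category

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            mm.classify_orientation(180.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0, 180))
    def test_partition_is_complete_and_exclusive(self, angle):
        assert mm.classify_orientation(angle) in (
            "Polarized", "Central", "Antipolarized"
        )


class TestOrientationAngles:
    def test_bead_orientation_fixed_points(self):
        b = np.zeros(3)
        a = np.array([0.0, 0.0, 5.0])
        assert mm.groove_orientation_bead(a, b, (0, 0, 2)) == pytest.approx(0.0)
        assert mm.groove_orientation_bead(a, b, (0, 0, -2)) == pytest.approx(180.0)
        assert mm.groove_orientation_bead(a, b, (0, 3, 0)) == pytest.approx(90.0)

    def test_bead_orientation_degenerate(self):
        with pytest.raises(mm.DegenerateGeometryError):
            mm.groove_orientation_bead((0, 0, 5), (0, 0, 0), (0, 0, 0))

    def test_dish_orientation_fixed_points(self):
        cell = np.array([3.0, 5.0, 5.0])
        assert mm.groove_orientation_dish(cell, (1.0, 5, 5), 0.0) == pytest.approx(0.0)
        assert mm.groove_orientation_dish(cell, (5.0, 5, 5), 0.0) == pytest.approx(180.0)
        assert mm.groove_orientation_dish(cell, (3.0, 7, 5), 0.0) == pytest.approx(90.0)

    def test_lobe_rotation_fixed_points(self):
        folded, raw = mm.lobe_rotation(((2, 0, 0), (2, 0, 4)))
        assert folded == pytest.approx(0.0) and raw == pytest.approx(90.0)
        folded, _ = mm.lobe_rotation(((0, 0, 1), (4, 0, 1)))
        assert folded == pytest.approx(90.0)
        with pytest.raises(mm.DegenerateGeometryError):
            mm.lobe_rotation(((1, 1, 1), (1, 1, 1)))


class TestGrooveDetection:
    def test_sphere_nucleus_has_no_groove(self):
        from test_segmentation import ball_mask

        sphere = ball_mask((40, 60, 60), (4.0, 2.0, 2.0), 1.6, (0.2, 0.07, 0.07))
        with pytest.raises(mm.GrooveNotFoundError, match="no groove"):
            mm.detect_groove(sphere)

    def test_groove_cm_displaced_toward_opening(self, bead_scene_clean, clean_masks, clean_groove):
        nucleus, _ = clean_masks
        nuc_cm = center_of_mass(nucleus)
        # opening faces +x (toward the bead at orientation 0)
        assert clean_groove.groove_cm[2] > nuc_cm[2] + 1.0

    def test_apices_within_300nm_of_ground_truth(self, bead_scene_clean, clean_groove):
        truth = bead_scene_clean.lobe_apices
        found = clean_groove.lobe_apices
        pairs = [
            min(np.linalg.norm(f - t) for t in truth) for f in found
        ]
        assert max(pairs) < 0.3

    def test_manual_roi_overrides_detection(self, clean_masks):
        nucleus, _ = clean_masks
        roi = Mask3D(np.zeros_like(nucleus.voxels), nucleus.voxel_size)
        roi.voxels[30:33, 38:46, 55:70] = True
        g = mm.detect_groove(nucleus, manual_roi=roi)
        assert g.source == "manual"


class TestGrooveDepthAndArea:
    def test_depth_point_on_baseline_is_zero(self, clean_masks):
        _, cell = clean_masks
        equator = int(np.argmax(cell.voxels.sum(axis=(1, 2))))
        geom = mm.GrooveGeometry(
            groove_mask=cell,  # placeholder mask, depth uses points only
            groove_cm=np.zeros(3),
            lobe_apices=(np.array([6.2, 4.0, 9.0]), np.array([6.2, 8.0, 9.0])),
            depth_point=np.array([6.2, 6.0, 9.0]),
            section_index=equator,
        )
        assert mm.groove_depth(geom, cell) == pytest.approx(0.0)

    def test_depth_normalization_arithmetic(self):
        """h = 2 um on a 10-um cell gives 0.2."""
        vox = np.zeros((1, 101, 101), bool)
        yy, xx = np.mgrid[:101, :101]
        vox[0] = (yy - 50) ** 2 + (xx - 50) ** 2 <= 50**2  # diameter 10 um at 0.1 um/px
        cell = Mask3D(vox, (0.1, 0.1, 0.1))
        geom = mm.GrooveGeometry(
            groove_mask=cell,
            groove_cm=np.zeros(3),
            lobe_apices=(np.array([0.0, 2.0, 8.0]), np.array([0.0, 8.0, 8.0])),
            depth_point=np.array([0.0, 5.0, 6.0]),
        )
        assert mm.groove_depth(geom, cell) == pytest.approx(0.2, abs=0.01)

    def test_phantom_depth_recovery(self, bead_scene_clean, clean_masks, clean_groove):
        _, cell = clean_masks
        depth = mm.groove_depth(clean_groove, cell)
        assert depth == pytest.approx(bead_scene_clean.groove_depth_true, abs=0.03)

    def test_groove_area_of_synthetic_notch(self):
        """A rectangular notch in a square nucleus is recovered exactly."""
        vox = np.zeros((3, 40, 40), bool)
        vox[:, 5:35, 5:35] = True
        vox[:, 15:25, 25:35] = False  # 10 x 10 px notch opening to +x
        nucleus = Mask3D(vox, (0.2, 0.1, 0.1))
        area = mm.groove_area(nucleus)
        assert area == pytest.approx(10 * 10 * 0.01, rel=0.05)

    def test_sphere_nucleus_area_missing_with_warning(self):
        from test_segmentation import ball_mask

        sphere = ball_mask((40, 60, 60), (4.0, 2.0, 2.0), 1.6, (0.2, 0.07, 0.07))
        with pytest.warns(UserWarning, match="groove area unavailable"):
            assert mm.groove_area(sphere) is None


class TestLampRing:
    def _puncta_stack(self, centers):
        img = np.zeros((1, 20, 60, 60))
        for z, y, x in centers:
            img[0, z, y, x] = 100.0
        return sm.ImageStack(img, (0.2, 0.1, 0.1), ("lamp1",))

    def test_all_inside_is_one(self):
        stack = self._puncta_stack([(10, 30, 30), (10, 32, 28)])
        bead = (2.0, 3.0, 3.0)
        assert mm.lamp_ring_fraction(stack, bead, 3.5) == pytest.approx(1.0)

    def test_none_inside_is_zero(self):
        stack = self._puncta_stack([(1, 2, 2)])
        bead = (2.0, 3.0, 3.0)
        assert mm.lamp_ring_fraction(stack, bead, 1.0) == pytest.approx(0.0)

    def test_zero_signal_is_nan_with_warning(self):
        stack = self._puncta_stack([])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(mm.lamp_ring_fraction(stack, (2.0, 3.0, 3.0)))

    def test_phantom_split_recovery(self, bead_scene_noisy, bead_stack_noisy):
        """40% of puncta placed inside the 3.5-um ring is recovered within 0.05."""
        frac = mm.lamp_ring_fraction(
            bead_stack_noisy,
            bead_scene_noisy.bead_cm,
            3.5,
            cell_mask=segment_channel(bead_stack_noisy, "lamp1", "noise_floor"),
        )
        assert frac == pytest.approx(
            bead_scene_noisy.lysosome_ring_fraction_true, abs=0.05
        )


class TestZDistribution:
    def _stack(self, img):
        return sm.ImageStack(img, (0.2, 0.1, 0.1), ("lamp1",))

    def test_uniform_signal_gives_ten_percent_each(self):
        stack = self._stack(np.ones((1, 12, 8, 8)))
        out = mm.z_distribution(stack, "lamp1", 0)
        np.testing.assert_allclose(out, 10.0)

    def test_all_signal_in_first_slice(self):
        img = np.zeros((1, 12, 8, 8))
        img[0, 0] = 7.0
        out = mm.z_distribution(self._stack(img), "lamp1", 0)
        np.testing.assert_allclose(out, [100.0] + [0.0] * 9)

    def test_sum_is_exactly_100(self, dish_stack, dish_scene):
        zi = int(round(dish_scene.synapse_z_um / dish_stack.voxel_size[0]))
        out = mm.z_distribution(dish_stack, "lamp1", zi)
        assert out.sum() == pytest.approx(100.0, abs=1e-9)
        assert (out >= 0).all()

    def test_all_zero_signal_gives_nans(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = mm.z_distribution(self._stack(np.zeros((1, 12, 8, 8))), "lamp1", 0)
        assert np.isnan(out).all()

    def test_too_few_slices_raises(self):
        with pytest.raises(ValueError, match="slices"):
            mm.z_distribution(self._stack(np.ones((1, 5, 8, 8))), "lamp1", 0)


class TestClusterPosition:
    VOX = (0.2, 0.1, 0.1)

    def _nucleus(self):
        vox = np.zeros((10, 40, 40), bool)
        vox[3:7, 10:30, 10:30] = True
        return Mask3D(vox, self.VOX)

    def test_straddling_cluster_counts_as_inside(self):
        lamp = np.zeros((10, 40, 40), bool)
        lamp[5, 28:36, 20] = True  # one voxel row overlaps the perinuclear shell
        assert mm.cluster_position(Mask3D(lamp, self.VOX), self._nucleus(), 0.5) == "inside"

    def test_distant_cluster_is_outside(self):
        lamp = np.zeros((10, 40, 40), bool)
        lamp[1, 36:39, 36:39] = True
        assert mm.cluster_position(Mask3D(lamp, self.VOX), self._nucleus(), 0.5) == "outside"

    def test_empty_lamp_mask_missing_with_warning(self):
        lamp = Mask3D(np.zeros((10, 40, 40), bool), self.VOX)
        with pytest.warns(UserWarning, match="undefined"):
            assert mm.cluster_position(lamp, self._nucleus()) is None


class TestRadialProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((1, 5, 64, 64), 7.0)
        stack = sm.ImageStack(img, (0.2, 0.05, 0.05), ("exo70",))
        _, mfi = mm.radial_profile(stack, "exo70", (0.4, 1.6, 1.6))
        np.testing.assert_allclose(mfi, 7.0)

    def test_point_source_profile_decreases(self):
        img = np.zeros((1, 3, 101, 101))
        img[0, 1, 50, 50] = 1000.0
        stack = sm.ImageStack(img, (0.2, 0.04, 0.04), ("exo70",))
        _, mfi = mm.radial_profile(stack, "exo70", (0.2, 2.0, 2.0))
        assert (np.diff(mfi) < 0).all()

    def test_gaussian_spot_matches_closed_form(self):
        """Disc-mean of A*exp(-r^2/2s^2) is A*2s^2(1-exp(-a^2/2s^2))/a^2."""
        s, A = 0.4, 100.0
        d = 0.02
        n = 301
        yy, xx = np.mgrid[:n, :n]
        r2 = ((yy - 150) * d) ** 2 + ((xx - 150) * d) ** 2
        img = (A * np.exp(-r2 / (2 * s**2)))[None, None]
        stack = sm.ImageStack(img, (0.2, d, d), ("exo70",))
        radii, mfi = mm.radial_profile(stack, "exo70", (0.0, 3.0, 3.0), r_max_um=2.0)
        expected = A * 2 * s**2 * (1 - np.exp(-(radii**2) / (2 * s**2))) / radii**2
        np.testing.assert_allclose(mfi, expected, rtol=0.03)

    def test_reference_outside_image_raises(self):
        img = np.ones((1, 3, 10, 10))
        stack = sm.ImageStack(img, (0.2, 0.1, 0.1), ("exo70",))
        with pytest.raises(ValueError, match="outside"):
            mm.radial_profile(stack, "exo70", (0.2, 5.0, 5.0))


class TestAntigenExtraction:
    def _stack(self, level):
        img = np.zeros((1, 4, 40, 40))
        img[0, :, 15:25, 15:25] = level
        return sm.ImageStack(img, (0.5, 0.1, 0.1), ("ova",))

    def test_unchanged_signal_is_zero_percent(self):
        stacks = [self._stack(100), self._stack(100)]
        pct = mm.antigen_extraction_pct(stacks, [(1.0, 2.0, 2.0)] * 2, 1.5)
        assert pct[1] == pytest.approx(0.0, abs=1e-9)

    def test_vanished_signal_is_hundred_percent(self):
        stacks = [self._stack(100), self._stack(0)]
        pct = mm.antigen_extraction_pct(stacks, [(1.0, 2.0, 2.0)] * 2, 1.5)
        assert pct[1] == pytest.approx(100.0)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError, match="t=0"):
            mm.antigen_extraction_pct([], [], 1.5)

    def test_monotone_on_noise_free_phantoms(self):
        cfg = sm.desk_scale_config(
            rng_seed=9, lysosome_count=0, noise=NOISE_OFF,
            channel_amplitudes={"ova": 500.0, "bead": 500.0},
        )
        series = sm.make_timecourse(cfg, [0, 1, 2, 3], [0.0, 0.2, 0.5, 0.9])
        pct = mm.antigen_extraction_pct(
            [s for _, _, s in series], [sc.bead_cm for _, sc, _ in series], 2.5
        )
        assert (np.diff(pct) > 0).all()
        np.testing.assert_allclose(pct, [0, 20, 50, 90], atol=0.5)


class TestSurfaceMfiAndDistances:
    def test_mfi_linearity(self):
        img = np.random.default_rng(0).random((1, 4, 20, 20))
        s1 = sm.ImageStack(img, (0.2, 0.1, 0.1), ("bcr",))
        s2 = sm.ImageStack(2 * img, (0.2, 0.1, 0.1), ("bcr",))
        assert mm.surface_mfi(s2) == pytest.approx(2 * mm.surface_mfi(s1))

    def test_zero_channel_gives_zero(self):
        stack = sm.ImageStack(np.zeros((1, 4, 20, 20)), (0.2, 0.1, 0.1), ("bcr",))
        assert mm.surface_mfi(stack) == 0.0

    def test_empty_region_raises(self):
        stack = sm.ImageStack(np.ones((1, 4, 20, 20)), (0.2, 0.1, 0.1), ("bcr",))
        with pytest.raises(Exception, match="empty"):
            mm.surface_mfi(stack, region2d=np.zeros((20, 20), bool))

    def test_synapse_distance_345(self):
        assert mm.synapse_center_distance((9.0, 0, 0), (0.0, 3, 4)) == pytest.approx(5.0)

    def test_synapse_distance_ignores_z(self):
        assert mm.synapse_center_distance((9.0, 1, 1), (0.0, 1, 1)) == 0.0


class TestRigidMotionEquivariance:
    def test_rotation_by_90_degrees_preserves_measures(
        self, bead_cfg_noisy, bead_scene_noisy, bead_stack_noisy
    ):
        """Rotating the stack 90 deg in xy leaves angles and indexes unchanged."""
        stack = bead_stack_noisy
        rot = sm.ImageStack(
            np.rot90(stack.intensities, k=1, axes=(2, 3)).copy(),
            stack.voxel_size,
            stack.channel_roles,
        )
        rec0 = sm.analyze_cell(stack, cell_id="orig")
        rec1 = sm.analyze_cell(rot, cell_id="rot")
        assert rec1.groove_angle_deg == pytest.approx(rec0.groove_angle_deg, abs=2.0)
        assert rec1.mtoc_polarity_index == pytest.approx(
            rec0.mtoc_polarity_index, abs=0.05
        )
        assert rec1.lamp_ring_frac == pytest.approx(rec0.lamp_ring_frac, abs=0.05)
        assert rec1.groove_depth_norm == pytest.approx(
            rec0.groove_depth_norm, abs=0.05
        )

    def test_translation_preserves_measures(self, bead_stack_noisy):
        stack = bead_stack_noisy
        shifted = sm.ImageStack(
            np.roll(stack.intensities, shift=(3, -4), axis=(2, 3)),
            stack.voxel_size,
            stack.channel_roles,
        )
        rec0 = sm.analyze_cell(stack, cell_id="orig")
        rec1 = sm.analyze_cell(shifted, cell_id="shift")
        assert rec1.groove_angle_deg == pytest.approx(rec0.groove_angle_deg, abs=2.0)
        assert rec1.mtoc_polarity_index == pytest.approx(
            rec0.mtoc_polarity_index, abs=0.05
        )
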