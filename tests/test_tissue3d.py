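import numpy as np
import pytest

from paleoattrib import synthetic as syn
from paleoattrib.io_core import BACKGROUND, DENTINE, ENAMEL, LabeledVolume, Plane
from paleoattrib.tissue3d import (
    BifurcationNotFound,
    crop_between_planes,
    find_bifurcation_level,
    fit_plane,
    hmh_threshold,
    lateral_tissue_proportions,
    split_root,
    vbi,
)


class TestHmhThreshold:
    @pytest.mark.parametrize("lo,hi,expected", [(0, 100, 50.0), (7.5, 7.5, 7.5)])
    def test_midpoint(self, lo, hi, expected):
        assert hmh_threshold(lo, hi) == expected

    def test_reversed_arguments_rejected(self):
        with pytest.raises(ValueError):
            hmh_threshold(10, 5)

    def test_two_material_misclassification_below_one_percent(self, rng):
        # Gaussian-noise grayscale phantom: air mean 30, mineral mean 170, sd 10
        truth = rng.random((40, 40, 40)) < 0.5
        gray = np.where(truth, 170.0, 30.0) + rng.normal(0, 10, truth.shape)
        seg = gray >= hmh_threshold(30, 170)
        assert np.mean(seg != truth) < 0.01


class TestFitPlane:
    def test_constant_z_points(self):
        pts = [(0, 0, 2.0), (1, 0, 2.0), (0, 1, 2.0), (3, 4, 2.0)]
        p = fit_plane(pts, occlusal_direction=(0, 0, 1))
        np.testing.assert_allclose(p.normal, [0, 0, 1], atol=1e-12)
        assert p.offset == pytest.approx(2.0)

    def test_exact_oblique_plane_recovered(self):
        pts = np.array([(3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 1, 1)], float)
        p = fit_plane(pts, occlusal_direction=(1, 1, 1))
        np.testing.assert_allclose(p.normal, np.ones(3) / np.sqrt(3), atol=1e-9)
        assert p.offset == pytest.approx(np.sqrt(3), abs=1e-9)

    def test_noisy_plane_normal_within_one_degree(self, rng):
        n = np.array([1.0, 2.0, 3.0])
        n /= np.linalg.norm(n)
        basis = np.linalg.svd(n[None])[2][1:]
        uv = rng.uniform(-5, 5, (200, 2))
        pts = uv @ basis + 1.5 * n + rng.normal(0, 0.01, (200, 1)) * n
        p = fit_plane(pts, occlusal_direction=n)
        angle = np.degrees(np.arccos(np.clip(p.normal @ n, -1, 1)))
        assert angle < 1.0

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_plane(pts)


def unit_cube_volume(vs=0.05):
    n = int(round(1.0 / vs))
    return LabeledVolume(np.full((n, n, n), DENTINE, dtype=np.int16), vs)


class TestCropBetweenPlanes:
    def test_planes_outside_bounding_box_identity(self):
        vol = unit_cube_volume()
        out = crop_between_planes(vol, Plane((0, 0, 1), -5.0), Plane((0, 0, 1), 5.0))
        np.testing.assert_array_equal(out.labels, vol.labels)

    def test_coincident_planes_empty(self):
        vol = unit_cube_volume()
        out = crop_between_planes(vol, Plane((0, 0, 1), 0.5), Plane((0, 0, 1), 0.5))
        assert not out.labels.any()

    def test_slab_volume_matches_analytic(self):
        vol = unit_cube_volume(vs=0.05)
        out = crop_between_planes(vol, Plane((0, 0, 1), 0.25), Plane((0, 0, 1), 0.75))
        got = out.volume_mm3(DENTINE)
        assert got == pytest.approx(0.5, abs=0.05**1 * 1.0 * 1.0)  # one voxel layer

    def test_split_conservation_is_exact(self, coarse_phantom):
        _, vol, truth = coarse_phantom
        lo, mid, up = (Plane((0, 0, 1), z) for z in (0.0, truth["z_bifurcation"], 50.0))
        full = crop_between_planes(vol, lo, up)
        a = crop_between_planes(vol, lo, mid)
        b = crop_between_planes(vol, mid, up)
        for lbl in (1, 2, 3):
            assert a.volume_mm3(lbl) + b.volume_mm3(lbl) == full.volume_mm3(lbl)

    def test_non_parallel_planes_rejected(self):
        vol = unit_cube_volume()
        with pytest.raises(ValueError, match="parallel"):
            crop_between_planes(vol, Plane((0, 0, 1), 0.2), Plane((0, 1e-3, 1), 0.8))

    def test_input_volume_unmodified(self):
        vol = unit_cube_volume()
        before = vol.labels.copy()
        crop_between_planes(vol, Plane((0, 0, 1), 0.25), Plane((0, 0, 1), 0.75))
        np.testing.assert_array_equal(vol.labels, before)


@pytest.fixture(scope="module")
def shell():
    # coarse concentric-shell crown phantom (unit tests; the acceptance
    # suite runs the fine-voxel version)
    vol, truth = syn.cylindrical_shell_phantom(5.0, 4.0, 4.0, 0.1)
    crop = crop_between_planes(
        vol, Plane((0, 0, 1), truth["z_base"]), Plane((0, 0, 1), truth["z_top"])
    )
    return crop, truth


class TestLateralTissueProportions:
    def test_laet_close_to_analytic_shell_value(self, shell):
        crop, truth = shell
        tp = lateral_tissue_proportions(crop)
        assert tp.laet_3d == pytest.approx(truth["laet"], rel=0.05)

    def test_scaling_doubles_laet_keeps_lret(self, shell):
        crop, truth = shell
        tp1 = lateral_tissue_proportions(crop)
        vol2, truth2 = syn.cylindrical_shell_phantom(10.0, 8.0, 8.0, 0.2)
        crop2 = crop_between_planes(
            vol2, Plane((0, 0, 1), truth2["z_base"]), Plane((0, 0, 1), truth2["z_top"])
        )
        tp2 = lateral_tissue_proportions(crop2)
        assert tp2.laet_3d == pytest.approx(2 * tp1.laet_3d, rel=0.02)
        assert tp2.lret_3d == pytest.approx(tp1.lret_3d, rel=0.02)

    def test_enamel_free_volume_rejected(self):
        vol = unit_cube_volume(0.1)
        with pytest.raises(ValueError, match="enamel"):
            lateral_tissue_proportions(vol)

    def test_face_count_estimator_is_exact_on_flat_interface(self):
        # two half-spaces meeting on an axis-aligned plane: staircase-free,
        # so the face count with correction 1.0 gives the exact area
        lab = np.full((20, 20, 20), ENAMEL, dtype=np.int16)
        lab[:, :, 10:] = DENTINE
        vol = LabeledVolume(lab, 0.1)
        tp = lateral_tissue_proportions(vol, area_method="face_count",
                                        face_count_correction=1.0)
        assert tp.s_edj_lateral == pytest.approx(2.0 * 2.0)


class TestSplitRootAndVbi:
    def test_phantom_volumes_within_two_percent(self, coarse_phantom):
        spec, vol, truth = coarse_phantom
        cerv = Plane((0, 0, 1), truth["z_cervix"])
        v_c, v_b = split_root(vol, cerv, spec.stem_height)
        assert v_c == pytest.approx(truth["stem_total"], rel=0.02)
        assert v_b == pytest.approx(truth["branch_total"], rel=0.02)

    def test_stem_plus_branch_equals_total_root_exactly(self, coarse_phantom):
        spec, vol, truth = coarse_phantom
        cerv = Plane((0, 0, 1), truth["z_cervix"])
        v_c, v_b = split_root(vol, cerv, spec.stem_height)
        total = sum(vol.volume_mm3(l) for l in (1, 2, 3))  # no crown: all is root
        assert v_c + v_b == pytest.approx(total, abs=1e-9)

    def test_plane_at_cervix_gives_zero_stem(self, coarse_phantom):
        _, vol, truth = coarse_phantom
        cerv = Plane((0, 0, 1), truth["z_cervix"])
        v_c, v_b = split_root(vol, cerv, 0.0)
        assert v_c == 0.0 and v_b > 0

    def test_plane_at_apex_gives_zero_branch(self, coarse_phantom):
        spec, vol, truth = coarse_phantom
        cerv = Plane((0, 0, 1), truth["z_cervix"])
        apex = spec.stem_height + spec.branch_height
        v_c, v_b = split_root(vol, cerv, apex)
        assert v_b == 0.0 and v_c > 0

    def test_level_outside_root_rejected(self, coarse_phantom):
        _, vol, truth = coarse_phantom
        cerv = Plane((0, 0, 1), truth["z_cervix"])
        with pytest.raises(ValueError, match="outside root extent"):
            split_root(vol, cerv, 100.0)

    def test_automatic_bifurcation_detection(self, coarse_phantom):
        spec, vol, truth = coarse_phantom
        cerv = Plane((0, 0, 1), truth["z_cervix"])
        level = find_bifurcation_level(vol, cerv)
        assert level == pytest.approx(spec.stem_height, abs=2 * vol.voxel_size)

    def test_single_root_has_no_bifurcation(self):
        spec = syn.PhantomSpec(n_branches=1, branch_radius=2.0, crown_radius=None,
                               voxel_size=0.2)
        vol, truth = syn.simulate_tooth_phantom(spec)
        cerv = Plane((0, 0, 1), truth["z_cervix"])
        with pytest.raises(BifurcationNotFound):
            find_bifurcation_level(vol, cerv)

    @pytest.mark.parametrize(
        "vc,vb,expected",
        [(502.6, 234.2, 68.2), (3.3, 3.3, 50.0), (7.0, 0.0, 100.0)],
    )
    def test_vbi_values(self, vc, vb, expected):
        assert vbi(vc, vb) == pytest.approx(expected, abs=0.05)

    def test_vbi_scale_invariant(self):
        assert vbi(502.6, 234.2) == pytest.approx(vbi(5.026, 2.342))

    def test_vbi_zero_total_rejected(self):
        with pytest.raises(ValueError):
            vbi(0.0, 0.0)
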