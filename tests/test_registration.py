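import numpy as np
import pytest

import bridgekit as bk
from bridgekit.registration import heldout_rmse


def _random_landmarks(rng, n=12, span=500.0):
    return rng.uniform(0, span, (n, 3))


class TestLandmarkFits:
    def test_rigid_recovers_generating_rotation_translation(self, rng):
        fixed = _random_landmarks(rng)
        true = bk.rigid_from_euler((30.0, 0.0, 0.0), (10.0, 20.0, 0.0))
        lms = bk.LandmarkSet(fixed, true.apply(fixed))
        fit = bk.fit_landmark_transform(lms, "rigid")
        assert np.abs(fit.matrix - true.matrix).max() < 1e-6
        assert np.abs(fit.translation - true.translation).max() < 1e-6
        # proper rotation
        assert np.allclose(fit.matrix @ fit.matrix.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(fit.matrix) == pytest.approx(1.0)

    def test_similarity_recovers_scale(self, rng):
        fixed = _random_landmarks(rng)
        rot = bk.rigid_from_euler((12.0, -8.0, 5.0), (0, 0, 0)).matrix
        true = bk.AffineTransform(1.7 * rot, (5.0, -3.0, 2.0), kind="similarity")
        lms = bk.LandmarkSet(fixed, true.apply(fixed))
        fit = bk.fit_landmark_transform(lms, "similarity")
        assert fit.scale == pytest.approx(1.7, abs=1e-9)
        assert np.abs(fit.matrix - true.matrix).max() < 1e-6

    def test_affine_recovers_general_matrix(self, rng):
        fixed = _random_landmarks(rng)
        matrix = np.eye(3) + rng.normal(scale=0.1, size=(3, 3))
        true = bk.AffineTransform(matrix, (4.0, 5.0, 6.0))
        lms = bk.LandmarkSet(fixed, true.apply(fixed))
        fit = bk.fit_landmark_transform(lms, "affine")
        assert np.abs(fit.matrix - true.matrix).max() < 1e-8

    def test_rigid_fit_matches_simpleitk_oracle(self, rng):
        """Independent cross-check of the closed-form rigid fit against
        SimpleITK's landmark-based initializer."""
        sitk = pytest.importorskip("SimpleITK")
        fixed = _random_landmarks(rng, n=8)
        true = bk.rigid_from_euler((11.0, 7.0, -4.0), (40.0, -25.0, 60.0))
        moving = true.apply(fixed) + rng.normal(scale=2.0, size=fixed.shape)
        fit = bk.fit_landmark_transform(bk.LandmarkSet(fixed, moving), "rigid")

        tx = sitk.LandmarkBasedTransformInitializer(
            sitk.VersorRigid3DTransform(),
            list(fixed[:, ::-1].ravel()),  # sitk expects (x, y, z)
            list(moving[:, ::-1].ravel()),
        )
        probe = rng.uniform(0, 500, (20, 3))
        ours = fit.apply(probe)
        theirs = np.array(
            [list(reversed(tx.TransformPoint(tuple(p[::-1])))) for p in probe]
        )
        assert np.abs(ours - theirs).max() < 1e-3

    def test_tps_interpolates_landmarks_exactly(self, rng):
        fixed = _random_landmarks(rng, n=10)
        moving = fixed + rng.normal(scale=30.0, size=fixed.shape)
        fit = bk.fit_landmark_transform(bk.LandmarkSet(fixed, moving), "tps")
        assert np.abs(fit.apply(fixed) - moving).max() < 1e-6

    def test_tps_of_identity_pairs_has_zero_warp(self, rng):
        fixed = _random_landmarks(rng, n=8)
        fit = bk.fit_landmark_transform(bk.LandmarkSet(fixed, fixed), "tps")
        assert np.abs(fit.weights).max() < 1e-9
        assert np.allclose(fit.affine[1:], np.eye(3), atol=1e-9)
        assert np.allclose(fit.affine[0], 0.0, atol=1e-6)

    def test_tps_on_affine_pairs_has_no_bending_energy(self, rng):
        fixed = _random_landmarks(rng, n=9)
        affine = bk.AffineTransform(np.eye(3) + rng.normal(scale=0.05, size=(3, 3)),
                                    (10.0, 0.0, -5.0))
        fit = bk.fit_landmark_transform(
            bk.LandmarkSet(fixed, affine.apply(fixed)), "tps"
        )
        assert abs(fit.bending_energy) < 1e-9

    def test_collinear_points_named_degenerate(self):
        fixed = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3.0]]) * 100
        with pytest.raises(ValueError, match="collinear"):
            bk.fit_landmark_transform(
                bk.LandmarkSet(fixed, fixed + 5), "affine"
            )

    def test_too_few_landmarks_rejected(self, rng):
        fixed = _random_landmarks(rng, n=3)
        with pytest.raises(ValueError, match="tps"):
            bk.fit_landmark_transform(bk.LandmarkSet(fixed, fixed + 1), "tps")


class TestTransformAlgebra:
    def test_translation_and_its_inverse_compose_to_identity(self, rng):
        t = bk.AffineTransform(np.eye(3), (1.0, 2.0, 3.0))
        composed = bk.compose_transforms([t, t.inverse()])
        pts = rng.uniform(0, 100, (10, 3))
        assert np.abs(composed.apply(pts) - pts).max() < 1e-12

    def test_rigid_composition_equals_matrix_product(self, rng):
        a = bk.rigid_from_euler((10, 5, 0), (1, 2, 3))
        b = bk.rigid_from_euler((-3, 12, 7), (4, -5, 6))
        composed = bk.compose_transforms([a, b])
        assert isinstance(composed, bk.AffineTransform)
        assert np.allclose(composed.matrix, b.matrix @ a.matrix)
        pts = rng.uniform(0, 100, (10, 3))
        assert np.abs(composed.apply(pts) - b.apply(a.apply(pts))).max() < 1e-9

    def test_chain_through_mid_space_matches_direct(self, rng):
        """Bridging through an intermediate frame (in vivo → ex vivo →
        microscopy) reproduces the direct mapping."""
        fixed = _random_landmarks(rng, n=10)
        t1 = bk.rigid_from_euler((8, 0, 0), (50, 0, 0))
        mid = t1.apply(fixed)
        t2 = bk.fit_landmark_transform(
            bk.LandmarkSet(mid, mid + rng.normal(scale=20, size=mid.shape)), "tps"
        )
        chain = bk.compose_transforms([t1, t2])
        assert np.abs(chain.apply(fixed) - t2.apply(t1.apply(fixed))).max() < 1e-9

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            bk.compose_transforms([])

    def test_dimension_mismatch_rejected(self):
        t = bk.identity_transform(3)
        with pytest.raises(ValueError, match="dimension"):
            t.apply(np.zeros((2, 2)))

    def test_json_round_trip(self, rng, tmp_path):
        fixed = _random_landmarks(rng, n=8)
        fit = bk.fit_landmark_transform(
            bk.LandmarkSet(fixed, fixed + rng.normal(scale=10, size=fixed.shape)),
            "tps",
        )
        path = tmp_path / "transform.json"
        bk.transform_to_json(fit, path)
        back = bk.transform_from_json(path)
        pts = rng.uniform(0, 400, (20, 3))
        assert np.abs(back.apply(pts) - fit.apply(pts)).max() < 1e-9


class TestResampling:
    def test_identity_same_grid_is_exact(self, random_volume):
        out = bk.resample_volume(
            random_volume, bk.identity_transform(3), random_volume, "nearest"
        )
        assert np.array_equal(out.data, random_volume.data)

    def test_one_voxel_translation_matches_index_shift(self, random_volume):
        shift = bk.AffineTransform(np.eye(3), (random_volume.spacing[0], 0, 0))
        out = bk.resample_volume(
            random_volume, shift, random_volume, "linear"
        )
        # pull-back by +1 voxel in z: output slice i shows input slice i+1
        assert np.allclose(out.data[:-1], random_volume.data[1:], atol=1e-12)
        assert np.allclose(out.data[-1], 0.0)  # border fill

    def test_constant_volume_stays_constant_inside_field(self, random_volume):
        const = random_volume.with_data(np.full(random_volume.shape, 7.0))
        rot = bk.rigid_from_euler((4.0, 0, 0), (0, 0, 0))
        out = bk.resample_volume(const, rot, const, "linear")
        interior = out.data[2:-2, 2:-2, 2:-2]
        inside = interior[interior > 0]
        assert inside.size and np.allclose(inside, 7.0)


class TestReslice:
    def test_normal_along_z_is_identity(self, random_volume):
        out, transform = bk.reslice_to_plane(random_volume, (0, 0, 0), (1, 0, 0))
        assert out.shape == random_volume.shape
        assert np.abs(out.data - random_volume.data).max() < 1e-9

    def test_axis_aligned_normal_permutes_shape(self, random_volume):
        out, _ = bk.reslice_to_plane(random_volume, (0, 0, 0), (0, 1, 0))
        assert sorted(out.shape) == sorted(random_volume.shape)
        assert out.shape[0] == random_volume.shape[1]

    def test_returned_transform_maps_new_frame_to_old(self, random_volume, rng):
        out, transform = bk.reslice_to_plane(
            random_volume, (10.0, 20.0, 5.0), (0.3, 0.8, 0.5)
        )
        # new-frame voxel centers map to world positions inside the old frame
        pts_new = out.index_to_world(rng.uniform(0, 3, (10, 3)))
        pts_old = transform.apply(pts_new)
        back = transform.inverse().apply(pts_old)
        assert np.abs(back - pts_new).max() < 1e-6

    def test_zero_normal_rejected(self, random_volume):
        with pytest.raises(ValueError):
            bk.reslice_to_plane(random_volume, (0, 0, 0), (0, 0, 0))


class TestMatchGridXY:
    def test_upscale_shape_arithmetic(self):
        vol = bk.Volume(np.zeros((2, 4, 4)), (100.0, 100.0, 100.0))
        out = bk.match_grid_xy(vol, 25.0)
        assert out.shape == (2, 16, 16)
        assert out.spacing == (100.0, 25.0, 25.0)

    def test_constant_preserved(self):
        vol = bk.Volume(np.full((2, 4, 4), 3.0), (100.0, 100.0, 100.0))
        out = bk.match_grid_xy(vol, 25.0)
        assert np.allclose(out.data, 3.0)

    def test_linear_ramp_preserved_exactly(self):
        x = np.arange(6) * 100.0
        ramp = np.broadcast_to(x, (2, 6, 6)).copy()
        vol = bk.Volume(ramp, (100.0, 100.0, 100.0))
        out = bk.match_grid_xy(vol, 20.0)
        expected = out.voxel_centers()[..., 2] - 50.0 + 0.0  # world x minus edge
        # ramp value equals world-x of the voxel center minus origin offset
        world_x = out.voxel_centers()[..., 2]
        assert np.abs(out.data - (world_x - vol.origin[2])).max() < 1e-9

    def test_world_extent_preserved(self):
        vol = bk.Volume(np.zeros((2, 5, 7)), (100.0, 90.0, 110.0))
        out = bk.match_grid_xy(vol, 30.0)
        assert np.all(np.abs(out.world_extent() - vol.world_extent()) <= 30.0)


class TestLongitudinalRegistration:
    def test_self_registration_is_identity(self):
        zz, yy, xx = np.mgrid[:16, :16, :16]
        data = np.exp(-((zz - 8) ** 2 + (yy - 7) ** 2 + (xx - 9) ** 2) / 20.0)
        ref = bk.Volume(data, (20.0, 20.0, 20.0))
        t = bk.register_longitudinal(ref, ref, n_starts=1)
        assert np.abs(t.matrix - np.eye(3)).max() < 1e-4
        assert np.abs(t.translation).max() < 1e-2

    def test_landmark_mode_recovers_small_pose(self, rng):
        fixed = _random_landmarks(rng, n=8)
        true = bk.rigid_from_euler((5.0, 0, 0), (30.0, 0, 0))
        lms = bk.LandmarkSet(fixed, true.apply(fixed))
        ref = bk.Volume(np.zeros((4, 4, 4)), (100.0,) * 3)
        t = bk.register_longitudinal(ref, ref, landmarks=lms)
        angle = np.degrees(
            np.arccos(np.clip((np.trace(t.matrix @ true.matrix.T) - 1) / 2, -1, 1))
        )
        assert angle < 0.1
        assert np.abs(t.translation - true.translation).max() < 2.0

    def test_intensity_mode_recovers_pose_noiseless(self):
        zz, yy, xx = np.mgrid[:24, :24, :24]
        data = np.exp(
            -((zz - 12) ** 2 / 40 + (yy - 10) ** 2 / 20 + (xx - 14) ** 2 / 30)
        ) + 0.5 * np.exp(
            -((zz - 6) ** 2 / 10 + (yy - 16) ** 2 / 14 + (xx - 8) ** 2 / 12)
        )
        ref = bk.Volume(data, (20.0,) * 3)
        true = bk.rigid_from_euler((5.0, 0, 0), (30.0, 0, 0))
        moving = bk.resample_volume(ref, true.inverse(), ref, "linear")
        rec = bk.register_longitudinal(
            bk.Volume(moving.data, ref.spacing), ref, n_starts=3
        )
        angle = np.degrees(
            np.arccos(np.clip((np.trace(rec.matrix @ true.matrix.T) - 1) / 2, -1, 1))
        )
        assert angle < 0.5
        probe = np.random.default_rng(0).uniform(100, 350, (50, 3))
        err = np.linalg.norm(rec.apply(probe) - true.apply(probe), axis=1)
        assert err.max() < 10.0  # half a 20 µm voxel


class TestRmseMetrics:
    def test_identical_points_give_zero(self):
        pts = np.array([[1.0, 2, 3], [4, 5, 6]])
        assert bk.landmark_rmse(pts, pts) == 0.0

    def test_three_four_five_offset(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[0.0, 3, 4]])
        assert bk.landmark_rmse(a, b) == pytest.approx(5.0)

    def test_mixed_offsets_hand_value(self):
        a = np.array([[0.0, 0, 0], [0, 0, 0]])
        b = np.array([[5.0, 0, 0], [0, 0, 0]])
        assert bk.landmark_rmse(a, b) == pytest.approx(np.sqrt(12.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bk.landmark_rmse(np.zeros((0, 3)), np.zeros((0, 3)))

    def test_interrater_identical_chains_zero(self, random_volume):
        grid = bk.make_rater_grid(random_volume, rows=10, cols=10)
        t = bk.rigid_from_euler((3.0, 0, 0), (5.0, 0, 0))
        assert bk.interrater_rmse(grid, t, t) == 0.0

    def test_interrater_pure_translation_difference(self, random_volume):
        grid = bk.make_rater_grid(random_volume, rows=10, cols=10)
        t1 = bk.identity_transform(3)
        t2 = bk.AffineTransform(np.eye(3), (0.0, 30.0, 40.0))
        assert bk.interrater_rmse(grid, t1, t2) == pytest.approx(50.0)

    def test_sampled_rmse_close_to_full_grid(self, random_volume, rng):
        grid = bk.make_rater_grid(random_volume, rows=50, cols=50)
        fixed = rng.uniform(0, 120, (10, 3))
        t1 = bk.identity_transform(3)
        t2 = bk.fit_landmark_transform(
            bk.LandmarkSet(fixed, fixed + rng.normal(scale=15, size=fixed.shape)),
            "tps",
        )
        full = bk.interrater_rmse(grid, t1, t2)
        sampled = bk.interrater_rmse(grid, t1, t2, sample_n=500, seed=7)
        assert abs(sampled - full) / full < 0.05


class TestHeldOutRecovery:
    def test_tps_below_one_mri_voxel_and_mode_ordering(self):
        """Elastic registration on smoothly warped phantoms: held-out RMSE
        under one 100 µm MRI voxel, and tps ≤ affine ≤ rigid on average."""
        vol = bk.Volume(np.zeros((8, 8, 8)), (75.0,) * 3)
        per_kind = {"rigid": [], "affine": [], "tps": []}
        for seed in range(3):
            scene = bk.generate_vessel_tree(
                (600.0,) * 3, n_roots=2, max_depth=3, radius_range=(12, 45),
                seed=seed,
            )
            assert len(scene.bifurcations) >= 10
            _, lms, _ = bk.apply_synthetic_deformation(
                vol,
                {"kind": "smooth", "amplitude": 80.0, "control_spacing": 500.0},
                seed=seed,
                landmark_points=scene.bifurcations,
            )
            for kind in per_kind:
                per_kind[kind].append(heldout_rmse(lms, kind))
        means = {k: np.mean(v) for k, v in per_kind.items()}
        assert means["tps"] < 100.0
        assert means["tps"] <= means["affine"] <= means["rigid"]
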