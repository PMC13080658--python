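import numpy as np
import pandas as pd
import pytest

import bridgekit as bk
from bridgekit.core import GeometryError


class TestGroupZByAverage:
    def test_groups_average_to_mri_depth(self, rng):
        stack = bk.Volume(rng.random((20, 4, 4)), (5.0, 1.0, 1.0))
        out = bk.group_z_by_average(stack, 100.0)
        assert out.shape == (1, 4, 4)
        assert np.allclose(out.data[0], stack.data.mean(axis=0))
        assert out.spacing[0] == 100.0

    def test_binary_stack_yields_volume_fraction(self):
        data = np.zeros((10, 2, 2))
        data[:5, 0, 0] = 1.0
        stack = bk.Volume(data, (10.0, 1.0, 1.0), dtype_role="density")
        out = bk.group_z_by_average(stack, 100.0)
        assert out.data[0, 0, 0] == pytest.approx(0.5)
        assert out.data[0, 1, 1] == 0.0

    def test_partial_trailing_group_dropped_with_warning(self, rng):
        stack = bk.Volume(rng.random((23, 2, 2)), (5.0, 1.0, 1.0))
        with pytest.warns(UserWarning, match="partial"):
            out = bk.group_z_by_average(stack, 100.0)
        assert out.shape[0] == 1

    def test_non_multiple_spacing_rejected(self, rng):
        stack = bk.Volume(rng.random((10, 2, 2)), (7.0, 1.0, 1.0))
        with pytest.raises(GeometryError, match="resample"):
            bk.group_z_by_average(stack, 100.0)

    def test_total_signal_conserved(self, rng):
        """Σ density · voxel volume is invariant under z-grouping (complete
        groups)."""
        stack = bk.Volume(rng.random((20, 6, 6)), (5.0, 2.0, 2.0),
                          dtype_role="density")
        out = bk.group_z_by_average(stack, 20.0)
        before = stack.data.sum() * stack.voxel_volume
        after = out.data.sum() * out.voxel_volume
        assert after == pytest.approx(before, rel=1e-12)


class TestDownsampleXYDensity:
    def _mri_grid(self, shape=(2, 4, 4), spacing=(100.0, 100.0, 100.0)):
        origin = tuple(s / 2 for s in spacing)
        return bk.Volume(np.zeros(shape), spacing, origin)

    def _micro(self, data, spacing=(100.0, 25.0, 25.0)):
        origin = (spacing[0] / 2, spacing[1] / 2, spacing[2] / 2)
        return bk.Volume(data, spacing, origin, dtype_role="density")

    def test_all_ones_stay_ones(self):
        out = bk.downsample_xy_density(
            self._micro(np.ones((2, 16, 16))), self._mri_grid()
        )
        assert np.allclose(out.data, 1.0)

    def test_all_zeros_stay_zeros(self):
        out = bk.downsample_xy_density(
            self._micro(np.zeros((2, 16, 16))), self._mri_grid()
        )
        assert np.allclose(out.data, 0.0)

    def test_linear_ramp_sampled_at_mri_centers(self):
        x_centers = 12.5 + np.arange(16) * 25.0
        ramp = np.broadcast_to(x_centers / 400.0, (2, 16, 16)).copy()
        out = bk.downsample_xy_density(self._micro(ramp), self._mri_grid())
        mri_x = 50.0 + np.arange(4) * 100.0
        assert np.abs(out.data[0, 0] - mri_x / 400.0).max() < 1e-9

    def test_z_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            bk.downsample_xy_density(
                self._micro(np.zeros((3, 16, 16))), self._mri_grid()
            )


class TestZNormalization:
    def test_example_value_and_stats(self):
        data = np.full((1, 2, 2), 120.0)
        mask_data = np.zeros((1, 2, 2), bool)
        mask_data[0, 0, :] = True
        data[0, 0, 0] = 90.0
        data[0, 0, 1] = 110.0  # NAGM mean 100, sd 10
        vol = bk.Volume(data, (100.0,) * 3)
        mask = bk.BinaryMask(mask_data, (100.0,) * 3)
        out, stats = bk.znormalize_nagm(vol, mask)
        assert stats.mean == pytest.approx(100.0)
        assert stats.sd == pytest.approx(10.0)
        assert out.data[0, 1, 0] == pytest.approx(2.0)

    def test_normalized_mask_voxels_have_zero_mean_unit_sd(self, rng):
        vol = bk.Volume(rng.normal(50, 7, size=(6, 6, 6)), (100.0,) * 3)
        mask = bk.BinaryMask(rng.random((6, 6, 6)) < 0.5, (100.0,) * 3)
        out, _ = bk.znormalize_nagm(vol, mask)
        assert abs(out.data[mask.data].mean()) < 1e-9
        assert abs(out.data[mask.data].std(ddof=0) - 1.0) < 1e-9
        # idempotent up to stats: renormalizing gives same result
        out2, _ = bk.znormalize_nagm(out, mask)
        assert abs(out2.data[mask.data].mean()) < 1e-9

    def test_constant_mask_rejected(self):
        vol = bk.Volume(np.full((2, 2, 2), 5.0), (1.0,) * 3)
        mask = bk.BinaryMask(np.ones((2, 2, 2), bool), (1.0,) * 3)
        with pytest.raises(ValueError, match="variance"):
            bk.znormalize_nagm(vol, mask)

    def test_empty_mask_rejected(self, rng):
        vol = bk.Volume(rng.random((2, 2, 2)), (1.0,) * 3)
        mask = bk.BinaryMask(np.zeros((2, 2, 2), bool), (1.0,) * 3)
        with pytest.raises(ValueError, match="empty"):
            bk.znormalize_nagm(vol, mask)


class TestT2StarFit:
    def test_noiseless_decay_recovered_exactly(self):
        te = [3.0, 6.0, 9.0, 12.0]
        vols = [
            bk.Volume(np.full((3, 3, 3), 1000.0 * np.exp(-t / 20.0)), (100.0,) * 3)
            for t in te
        ]
        t2, s0 = bk.fit_t2star_map(vols, te)
        assert np.abs(t2.data - 20.0).max() < 1e-6
        assert np.abs(s0.data - 1000.0).max() < 1e-6

    def test_constant_signal_masked_invalid(self):
        te = [3.0, 6.0, 9.0]
        vols = [bk.Volume(np.full((2, 2, 2), 500.0), (100.0,) * 3) for _ in te]
        t2, s0 = bk.fit_t2star_map(vols, te)
        assert np.isnan(t2.data).all()

    def test_recovery_within_5pct_at_snr_50(self, rng):
        te = np.array([3.0, 6.0, 9.0, 12.0, 15.0])
        true_t2 = 20.0
        s0 = 1000.0
        shape = (10, 10, 10)  # 1000 voxels
        vols = [
            bk.Volume(
                s0 * np.exp(-t / true_t2)
                + rng.normal(scale=s0 / 50.0, size=shape),
                (100.0,) * 3,
            )
            for t in te
        ]
        t2, _ = bk.fit_t2star_map(vols, te)
        valid = t2.data[np.isfinite(t2.data)]
        assert abs(np.median(valid) - true_t2) / true_t2 < 0.05

    def test_too_few_echoes_rejected(self):
        vols = [bk.Volume(np.ones((2, 2, 2)), (1.0,) * 3)] * 2
        with pytest.raises(ValueError):
            bk.fit_t2star_map(vols, [3.0, 6.0])


class TestExtractVoxelTable:
    def _setup(self, rng):
        shape = (3, 4, 5)
        spacing = (100.0,) * 3
        density = bk.Volume(rng.random(shape), spacing, dtype_role="density")
        intensity = bk.Volume(rng.normal(size=shape), spacing)
        labels = np.zeros(shape, int)
        labels.ravel()[rng.choice(np.prod(shape), 7, replace=False)] = 1
        return density, intensity, bk.LabelMask(labels, spacing)

    def test_one_row_per_labeled_voxel(self, rng):
        density, intensity, cats = self._setup(rng)
        table = bk.extract_voxel_table(
            {"glioma_density": density, "t2w_z": intensity}, cats
        )
        assert len(table) == 7

    def test_empty_mask_gives_empty_table(self, rng):
        density, intensity, _ = self._setup(rng)
        empty = bk.LabelMask(np.zeros(density.shape, int), density.spacing)
        table = bk.extract_voxel_table({"glioma_density": density}, empty)
        assert len(table) == 0

    def test_values_match_direct_indexing(self, rng):
        density, intensity, cats = self._setup(rng)
        table = bk.extract_voxel_table(
            {"glioma_density": density, "t2w_z": intensity}, cats
        )
        for row in table.itertuples():
            assert density.data[row.i, row.j, row.k] == row.glioma_density
            assert intensity.data[row.i, row.j, row.k] == row.t2w_z

    def test_geometry_mismatch_names_layer(self, rng):
        density, _, cats = self._setup(rng)
        other = bk.Volume(np.zeros((2, 2, 2)), (50.0,) * 3)
        with pytest.raises(GeometryError, match="bad_layer"):
            bk.extract_voxel_table({"bad_layer": other}, cats)

    def test_metadata_columns_added(self, rng):
        density, _, cats = self._setup(rng)
        table = bk.extract_voxel_table(
            {"glioma_density": density}, cats,
            metadata={"timepoint_days": 24, "subject_id": "m01"},
        )
        assert (table["timepoint_days"] == 24).all()
        assert (table["subject_id"] == "m01").all()


class TestDensityBins:
    def test_boundary_follows_half_open_convention(self):
        table = pd.DataFrame(
            {"glioma_density": [0.05, 1.0, 0.0, 0.25], "category": ["g"] * 4}
        )
        out = bk.bin_by_density(table)
        assert list(out["density_bin"]) == ["5-25%", "75-100%", "0-5%", "25-50%"]

    def test_normal_category_forced_to_without_glioma(self):
        table = pd.DataFrame(
            {"glioma_density": [0.4, 0.4], "category": ["normal", "glioma"]}
        )
        out = bk.bin_by_density(table)
        assert out["density_bin"].iloc[0] == "w/o glioma"
        assert out["glioma_density"].iloc[0] == 0.0
        assert out["density_bin"].iloc[1] == "25-50%"

    def test_bins_partition_the_table(self, rng):
        table = pd.DataFrame(
            {
                "glioma_density": rng.random(1000),
                "category": rng.choice(["normal", "glioma"], 1000),
            }
        )
        out = bk.bin_by_density(table)
        assert out["density_bin"].notna().all()
        assert out["density_bin"].value_counts().sum() == 1000

    def test_out_of_range_density_rejected(self):
        table = pd.DataFrame({"glioma_density": [1.2], "category": ["g"]})
        with pytest.raises(ValueError):
            bk.bin_by_density(table)


class TestGrowthRate:
    def test_rate_formula(self):
        spacing = (100.0,) * 3
        v0 = bk.Volume(np.full((2, 2, 2), 0.1), spacing, dtype_role="density")
        v1 = bk.Volume(np.full((2, 2, 2), 0.3), spacing, dtype_role="density")
        records = bk.compute_growth_rate([v0, v1], [0.0, 10.0])
        rates = [r.growth_rate for r in records]
        assert np.allclose(rates, 2.0)

    def test_constant_density_zero_rate(self):
        spacing = (100.0,) * 3
        v = bk.Volume(np.full((2, 2, 2), 0.5), spacing, dtype_role="density")
        records = bk.compute_growth_rate([v, v], [0.0, 5.0])
        assert all(r.growth_rate == 0.0 for r in records)

    def test_voxel_missing_from_one_mask_excluded(self):
        spacing = (100.0,) * 3
        v0 = bk.Volume(np.full((1, 2, 2), 0.1), spacing, dtype_role="density")
        v1 = bk.Volume(np.full((1, 2, 2), 0.2), spacing, dtype_role="density")
        m_all = bk.BinaryMask(np.ones((1, 2, 2), bool), spacing)
        m_partial = bk.BinaryMask(
            np.array([[[True, False], [True, True]]]), spacing
        )
        records = bk.compute_growth_rate(
            [v0, v1], [0.0, 10.0], overlap_masks=[m_all, m_partial]
        )
        by_index = {r.index: r for r in records}
        assert not by_index[(0, 0, 1)].overlap
        assert np.isnan(by_index[(0, 0, 1)].growth_rate)
        assert by_index[(0, 0, 0)].overlap
        assert by_index[(0, 0, 0)].growth_rate == pytest.approx(1.0)

    def test_zero_day_span_rejected(self):
        v = bk.Volume(np.zeros((1, 1, 1)), (1.0,) * 3)
        with pytest.raises(ValueError):
            bk.compute_growth_rate([v, v], [3.0, 3.0])


class TestGroupStats:
    def test_identical_groups_mannwhitney_p_near_one(self):
        table = pd.DataFrame(
            {"value": list(range(10)) * 2, "group": ["a"] * 10 + ["b"] * 10}
        )
        report = bk.group_stats(table, "value", "group", test="mannwhitney")
        assert report["pvalue"] > 0.9

    def test_welch_detects_huge_effect(self, rng):
        table = pd.DataFrame(
            {
                "value": np.concatenate(
                    [rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
                ),
                "group": ["a"] * 50 + ["b"] * 50,
            }
        )
        report = bk.group_stats(table, "value", "group", test="welch")
        assert report["pvalue"] < 1e-10

    def test_dunn_bonferroni_arithmetic(self, rng):
        table = pd.DataFrame(
            {
                "value": np.concatenate(
                    [rng.normal(m, 1, 20) for m in (0.0, 0.4, 1.0)]
                ),
                "group": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
            }
        )
        report = bk.group_stats(table, "value", "group", test="kruskal_dunn_bonf")
        pairwise = report["pairwise"]
        assert len(pairwise) == 3
        expected = np.minimum(1.0, 3 * pairwise["p_raw"])
        assert np.allclose(pairwise["p_adjusted"], expected)

    def test_anova_tukey_reports_all_pairs(self, rng):
        table = pd.DataFrame(
            {
                "value": rng.normal(size=60),
                "group": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
            }
        )
        report = bk.group_stats(table, "value", "group", test="anova_tukey")
        assert len(report["pairwise"]) == 3
        assert 0 <= report["pvalue"] <= 1

    def test_insufficient_groups_rejected(self):
        table = pd.DataFrame({"value": [1.0, 2.0], "group": ["a", "a"]})
        with pytest.raises(ValueError):
            bk.group_stats(table, "value", "group", test="welch")
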