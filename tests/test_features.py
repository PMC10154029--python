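import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwayaf.features import (
    FEATURE_COLUMNS,
    TABLE_COLUMNS,
    FeatureError,
    NucleusEstimate,
    build_feature_table,
    compute_ratio_volume,
    estimate_nucleus,
    extract_features,
    feret_diameters_2d,
    max_feret_bruteforce,
    paired_ratio_change,
)
from airwayaf.stack_io import LabelVolume, MultiChannelStack


def uniform_stack(shape, nadph=10.0, fad=10.0, voxel=(0.25, 0.25, 0.5)):
    return MultiChannelStack(
        nadph=np.full(shape, nadph),
        fad=np.full(shape, fad),
        shg=np.zeros(shape),
        voxel_size=voxel,
    )


def ellipsoid_mask(shape, center, semi):
    zz, yy, xx = np.indices(shape)
    cz, cy, cx = center
    sz, sy, sx = semi
    return ((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2 <= 1


class TestRatioVolume:
    def test_boundary_and_symmetry_voxels(self):
        stack = uniform_stack((2, 2, 2))
        stack.fad[0, 0, 0], stack.nadph[0, 0, 0] = 10.0, 0.0  # pure FAD
        rv = compute_ratio_volume(stack, floor=1.0)
        assert rv.ratio[0, 0, 0] == pytest.approx(1.0)
        assert rv.ratio[1, 1, 1] == pytest.approx(0.5)  # fad == nadph

    def test_below_floor_is_undefined_and_masked(self):
        stack = uniform_stack((2, 2, 2), nadph=0.05, fad=0.05)
        rv = compute_ratio_volume(stack, floor=1.0)
        assert not rv.defined_mask.any()
        assert np.isnan(rv.ratio).all()

    def test_invalid_floor(self):
        with pytest.raises(FeatureError, match="invalid floor"):
            compute_ratio_volume(uniform_stack((2, 2, 2)), floor=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_bounded_and_scale_invariant(self, seed, scale):
        """0 <= ratio <= 1 on the defined mask; multiplying both channels
        by any c > 0 leaves every defined ratio voxel unchanged."""
        rng = np.random.default_rng(seed)
        shape = (4, 6, 6)
        nadph = rng.uniform(0, 50, shape)
        fad = rng.uniform(0, 50, shape)
        stack = MultiChannelStack(nadph=nadph, fad=fad, shg=np.zeros(shape))
        rv = compute_ratio_volume(stack, floor=0.5)
        vals = rv.ratio[rv.defined_mask]
        assert ((vals >= 0) & (vals <= 1)).all()
        scaled = MultiChannelStack(
            nadph=nadph * scale, fad=fad * scale, shg=np.zeros(shape)
        )
        rv2 = compute_ratio_volume(scaled, floor=0.5 * scale)
        np.testing.assert_allclose(
            rv2.ratio[rv.defined_mask], rv.ratio[rv.defined_mask], rtol=1e-9
        )
        np.testing.assert_array_equal(rv2.defined_mask, rv.defined_mask)


class TestNucleusEstimate:
    def test_dark_ellipsoid_found_with_centroid(self):
        shape = (24, 24, 24)
        stack = uniform_stack(shape, nadph=50, fad=50)
        cell = ellipsoid_mask(shape, (12, 12, 12), (10, 10, 10))
        nuc_truth = ellipsoid_mask(shape, (10, 12, 12), (4, 4, 4))
        stack.nadph[nuc_truth] = 2.0
        stack.fad[nuc_truth] = 2.0
        nuc = estimate_nucleus(stack, cell)
        assert nuc_truth.sum() >= 150
        assert np.linalg.norm(np.array(nuc.centroid) - np.array((10, 12, 12))) <= 1.0
        assert nuc.mean_af < stack.total_autofluorescence()[cell].mean()

    def test_uniform_cell_has_no_nucleus(self):
        shape = (16, 16, 16)
        stack = uniform_stack(shape, nadph=50, fad=50)
        cell = ellipsoid_mask(shape, (8, 8, 8), (6, 6, 6))
        with pytest.raises(FeatureError, match="nucleus not found"):
            estimate_nucleus(stack, cell)

    def test_largest_dark_region_wins_over_void(self):
        shape = (24, 24, 24)
        stack = uniform_stack(shape, nadph=50, fad=50)
        cell = ellipsoid_mask(shape, (12, 12, 12), (11, 11, 11))
        nucleus = ellipsoid_mask(shape, (8, 12, 12), (4, 4, 4))  # ~200+ voxels
        void = ellipsoid_mask(shape, (17, 12, 12), (2.3, 2.3, 2.3))  # ~50 voxels
        for dark in (nucleus, void):
            stack.nadph[dark] = 2.0
            stack.fad[dark] = 2.0
        nuc = estimate_nucleus(stack, cell)
        assert nucleus.sum() > void.sum()
        assert nuc.centroid[0] == pytest.approx(8, abs=1.0)


class TestFeretAndExtraction:
    def test_voxelized_ellipsoid_lengths_and_aspects(self):
        # semi-axes (5, 2, 4) um at (0.25, 0.25, 0.5) um voxels
        shape = (40, 48, 64)
        voxel = (0.25, 0.25, 0.5)
        stack = uniform_stack(shape, nadph=40, fad=40, voxel=voxel)
        mask = ellipsoid_mask(shape, (20, 24, 32), (8, 8, 20))
        # semi (z=8 vox=4um, y=8 vox=2um, x=20 vox=5um)
        rv = compute_ratio_volume(stack, floor=1.0)
        fv = extract_features(stack, rv, mask, nucleus=None)
        assert fv.x_length == pytest.approx(10.0, abs=voxel[0])
        assert fv.y_length == pytest.approx(4.0, abs=voxel[1])
        assert fv.z_length == pytest.approx(8.0, abs=voxel[2])
        assert fv.aspect_xy == pytest.approx(fv.x_length / fv.y_length, abs=1e-12)
        assert fv.aspect_yz == pytest.approx(fv.y_length / fv.z_length, abs=1e-12)

    def test_lateral_translation_invariance_is_exact(self):
        shape = (20, 48, 48)
        voxel = (0.25, 0.25, 0.5)
        stack = uniform_stack(shape, nadph=40, fad=40, voxel=voxel)
        rv = compute_ratio_volume(stack, floor=1.0)
        base = ellipsoid_mask(shape, (10, 14, 14), (6, 8, 10))
        moved = np.roll(base, (9, 11), axis=(1, 2))
        fv1 = extract_features(stack, rv, base, nucleus=None)
        fv2 = extract_features(stack, rv, moved, nucleus=None)
        for name in FEATURE_COLUMNS:
            v1, v2 = getattr(fv1, name), getattr(fv2, name)
            assert (np.isnan(v1) and np.isnan(v2)) or v1 == v2

    def test_max_feret_matches_bruteforce_oracle(self, clean_flat_scene):
        """x_length equals the O(n^2) max pairwise distance of the XY
        projection (plus the one-pixel footprint), within one voxel."""
        scene = clean_flat_scene
        stack = scene.stack
        dx, dy, _ = stack.voxel_size
        rv = compute_ratio_volume(stack)
        for cid in scene.labels.ids():
            mask = scene.labels.mask(int(cid))
            fv = extract_features(stack, rv, mask, nucleus=None)
            zs, ys, xs = np.nonzero(mask)
            pts = np.unique(np.stack([ys * dy, xs * dx], 1), axis=0)
            brute = max_feret_bruteforce(pts)
            assert abs(fv.x_length - (brute + 0.5 * (dx + dy))) <= 1e-9
            assert abs(fv.x_length - brute) <= max(dx, dy)

    def test_dilation_never_shrinks_lengths(self):
        from scipy.ndimage import binary_dilation

        shape = (24, 32, 32)
        stack = uniform_stack(shape, nadph=40, fad=40)
        rv = compute_ratio_volume(stack, floor=1.0)
        mask = ellipsoid_mask(shape, (12, 16, 16), (5, 7, 9))
        grown = binary_dilation(mask)
        fv, fg = (extract_features(stack, rv, m, nucleus=None) for m in (mask, grown))
        assert fg.x_length >= fv.x_length
        assert fg.y_length >= fv.y_length
        assert fg.z_length >= fv.z_length

    def test_min_feret_of_rectangle(self):
        pts = np.array([[y, x] for y in range(3) for x in range(10)], float)
        max_f, min_f = feret_diameters_2d(pts)
        assert max_f == pytest.approx(np.hypot(9, 2))
        assert min_f == pytest.approx(2.0)

    def test_constant_ratio_cell_has_zero_sds(self):
        shape = (20, 24, 24)
        stack = uniform_stack(shape, nadph=30, fad=10)
        rv = compute_ratio_volume(stack, floor=1.0)
        mask = ellipsoid_mask(shape, (10, 12, 12), (7, 8, 8))
        fv = extract_features(stack, rv, mask, nucleus=None)
        assert fv.ratio == pytest.approx(0.25)
        assert fv.sd_top == 0.0 and fv.sd_bottom == 0.0
        assert np.isnan(fv.sd_ratio)

    def test_nuclear_position_unit_arithmetic(self):
        shape = (20, 24, 24)
        stack = uniform_stack(shape, nadph=30, fad=10, voxel=(0.25, 0.25, 0.5))
        rv = compute_ratio_volume(stack, floor=1.0)
        mask = ellipsoid_mask(shape, (10, 12, 12), (7, 8, 8))
        nuc = NucleusEstimate(centroid=(8.0, 12.0, 12.0), voxels=np.zeros((1, 3), int), mean_af=1.0)
        fv = extract_features(stack, rv, mask, nucleus=nuc, reference_z=0.0)
        assert fv.nuclear_position == pytest.approx(4.0)

    def test_cell_too_small(self):
        stack = uniform_stack((6, 6, 6))
        rv = compute_ratio_volume(stack, floor=1.0)
        mask = np.zeros((6, 6, 6), bool)
        mask[2, 2, 2] = True
        with pytest.raises(FeatureError, match="cell too small"):
            extract_features(stack, rv, mask, nucleus=None)


class TestFeatureTable:
    def test_empty_label_volume_gives_headed_empty_table(self):
        stack = uniform_stack((6, 8, 8))
        rv = compute_ratio_volume(stack, floor=1.0)
        table = build_feature_table(stack, rv, LabelVolume(labels=np.zeros((6, 8, 8), int)))
        assert len(table) == 0
        assert list(table.columns) == TABLE_COLUMNS

    def test_rows_ordered_by_label_with_types(self, clean_flat_scene):
        scene = clean_flat_scene
        rv = compute_ratio_volume(scene.stack)
        table = build_feature_table(
            scene.stack, rv, scene.labels, reference_z=scene.geometry.base_z
        )
        assert list(table.cell_id) == sorted(table.cell_id)
        assert set(table.cell_type) <= set(scene.labels.type_of.values())

    def test_aspect_identities_hold_on_every_row(self, clean_flat_scene):
        scene = clean_flat_scene
        rv = compute_ratio_volume(scene.stack)
        table = build_feature_table(scene.stack, rv, scene.labels)
        np.testing.assert_allclose(table.aspect_xy, table.x_length / table.y_length, rtol=1e-12)
        np.testing.assert_allclose(table.aspect_yz, table.y_length / table.z_length, rtol=1e-12)
        assert (table.x_length >= table.y_length).all()


class TestPairedComparison:
    def test_identical_conditions_mean_zero(self):
        ratios = {1: 0.5, 2: 0.6, 3: 0.7}
        res = paired_ratio_change(ratios, dict(ratios))
        assert res["mean_delta"] == 0.0
        assert np.isnan(res["p_value"])  # zero variance: t undefined

    def test_systematic_shift_detected(self, rng):
        before = pd.Series(rng.uniform(0.4, 0.6, 30), index=range(30))
        after = before - 0.1 + rng.normal(0, 0.005, 30)
        res = paired_ratio_change(before, after)
        assert res["mean_delta"] == pytest.approx(-0.1, abs=0.01)
        assert res["p_value"] < 1e-6

    def test_mismatched_ids_raise_pairing_error(self):
        with pytest.raises(FeatureError, match="pairing error"):
            paired_ratio_change({1: 0.5}, {2: 0.5})
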