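import numpy as np
import pytest

from conftest import SPACING, embedded, make_mask, make_volume, quantized_from_levels
from petrad.features import (
    COARSENESS_CAP,
    FEATURE_NAMES,
    compute_glcm,
    compute_glszm,
    compute_histogram_features,
    compute_nglcm,
    compute_ngldm,
    compute_ngtdm,
    compute_shape_features,
    compute_suv_features,
    extract_features,
    quantize,
)
from petrad.features.texture import ngtdm_table


def box_voi(values3d, pad=1):
    """Volume/mask pair: mask over the embedded core region."""
    values3d = np.asarray(values3d, dtype=float)
    vol = make_volume(embedded(values3d, pad))
    m = np.zeros(vol.shape, dtype=bool)
    sl = tuple(slice(pad, pad + n) for n in values3d.shape)
    m[sl] = True
    return vol, make_mask(m)


class TestSUVFeatures:
    def test_hundred_voxel_block(self):
        vol, mask = box_voi(np.full((4, 5, 5), 5.0))
        f = compute_suv_features(vol, mask)
        assert f["MTV"] == pytest.approx(100 * 2.73**2 * 3.27 / 1000, rel=1e-9)
        assert f["MTV"] == pytest.approx(2.4371, abs=1e-4)
        assert f["SUVmean"] == 5.0
        assert f["TLG"] == pytest.approx(12.1856, abs=2e-4)

    def test_min_max_mean(self):
        core = np.array([[[2.0, 4.0, 6.0]]])
        vol, mask = box_voi(core)
        f = compute_suv_features(vol, mask)
        assert f["SUVmax"] == 6.0
        assert f["SUVmean"] == 4.0

    def test_tlg_identity(self, rng):
        for _ in range(20):
            core = rng.random((3, 4, 5)) * 15 + 0.1
            vol, mask = box_voi(core)
            f = compute_suv_features(vol, mask)
            assert f["TLG"] == pytest.approx(f["SUVmean"] * f["MTV"], rel=1e-9)


class TestQuantize:
    def test_bin_arithmetic(self):
        core = np.zeros((1, 1, 4))
        core[0, 0] = [0.0, 1.0, 32.0, 63.9]
        vol, mask = box_voi(core)
        q = quantize(vol, mask, 64)
        sl = q.levels[1, 1, 1:5]
        assert sl[0] == 1  # min maps to level 1
        assert sl[1] == 2  # 1.0/63.9*64 = 1.0016 -> floor + 1
        assert sl[3] == 64  # max clamps into level N

    def test_constant_voi_all_level_one(self):
        vol, mask = box_voi(np.full((2, 2, 2), 7.0))
        q = quantize(vol, mask, 64)
        assert (q.levels[mask.mask] == 1).all()

    def test_extremes_map_to_bounds(self, rng):
        core = rng.random((4, 4, 4)) * 30
        vol, mask = box_voi(core)
        q = quantize(vol, mask, 64)
        lv = q.levels[mask.mask]
        vals = vol.values[mask.mask]
        assert lv[np.argmin(vals)] == 1
        assert lv[np.argmax(vals)] == 64


class TestHistogramFeatures:
    def test_constant_voi_degenerate(self):
        vol, mask = box_voi(np.full((2, 3, 2), 4.0))
        f = compute_histogram_features(vol, mask)
        assert f["HIST_ENTROPY"] == 0.0
        assert f["HIST_UNIFORMITY"] == 1.0
        assert f["HIST_SD"] == 0.0
        assert f["HIST_SKEWNESS"] == 0.0

    def test_uniform_64_bins(self):
        core = np.arange(64, dtype=float).reshape(4, 4, 4)
        vol, mask = box_voi(core)
        f = compute_histogram_features(vol, mask, n_bins=64)
        assert f["HIST_ENTROPY"] == pytest.approx(6.0)
        assert f["HIST_UNIFORMITY"] == pytest.approx(1 / 64)

    def test_closed_form_moments(self):
        core = np.array([[[1.0, 1.0], [1.0, 5.0]]])
        vol, mask = box_voi(core)
        f = compute_histogram_features(vol, mask)
        assert f["HIST_MEAN"] == pytest.approx(2.0)
        assert f["HIST_SD"] == pytest.approx(np.sqrt(3.0))
        assert f["HIST_SKEWNESS"] == pytest.approx(2.0 / np.sqrt(3.0), rel=1e-9)
        assert f["HIST_SKEWNESS"] == pytest.approx(1.1547, abs=1e-4)


class TestShapeFeatures:
    def test_filled_box_solidity_one(self):
        vol, mask = box_voi(np.full((3, 3, 3), 1.0))
        f = compute_shape_features(mask)
        assert f["SOLIDITY"] == pytest.approx(1.0)

    def test_notched_slab_solidity(self):
        # 3x3x1 slab minus an edge-midpoint voxel: the hull of the 8 remaining
        # centers still contains the removed center -> 8/9
        core = np.ones((3, 3, 1))
        core[1, 2, 0] = 0.0
        vol = make_volume(embedded(core))
        m = embedded(core).astype(bool)
        mask = make_mask(m)
        f = compute_shape_features(mask)
        assert f["SOLIDITY"] == pytest.approx(8 / 9, abs=1e-9)

    def test_notched_slab_matches_brute_force_hull(self):
        # brute-force oracle: point-in-2D-hull test over the 9 grid centers
        from scipy.spatial import ConvexHull

        pts = np.array(
            [
                (i * SPACING[0], j * SPACING[1])
                for i in range(3)
                for j in range(3)
                if not (i == 1 and j == 2)
            ]
        )
        hull = ConvexHull(pts)
        inside = 0
        for i in range(3):
            for j in range(3):
                p = np.array([i * SPACING[0], j * SPACING[1]])
                vals = p @ hull.equations[:, :-1].T + hull.equations[:, -1]
                inside += (vals <= 1e-9).all()
        assert inside == 9  # removed center is inside the hull

    def test_elongation_of_rod_less_than_cube(self):
        vol_c, mask_c = box_voi(np.ones((3, 3, 3)))
        vol_r, mask_r = box_voi(np.ones((9, 2, 2)))
        f_c = compute_shape_features(mask_c)
        f_r = compute_shape_features(mask_r)
        assert f_r["ELONGATION"] < f_c["ELONGATION"] <= 1.0

    def test_surface_area_of_unit_cube_block(self):
        vol, mask = box_voi(np.ones((2, 2, 2)))
        f = compute_shape_features(mask)
        dx, dy, dz = SPACING
        expected = 2 * (4 * dy * dz + 4 * dx * dz + 4 * dx * dy)
        assert f["SURFACE_AREA"] == pytest.approx(expected)


class TestGLSZM:
    def test_single_zone(self):
        q = quantized_from_levels(embedded(np.full((2, 2, 1), 3)).astype(int), 4)
        mat, f = compute_glszm(q)
        assert mat[2, 3] == 1  # level 3, size 4
        assert mat.sum() == 1
        assert f["GLSZM_ZP"] == pytest.approx(0.25)

    def test_all_distinct(self):
        core = np.array([[[1], [2]], [[3], [4]]])
        q = quantized_from_levels(embedded(core), 4)
        _, f = compute_glszm(q)
        assert f["GLSZM_ZP"] == pytest.approx(1.0)

    def test_three_by_three_fixture(self):
        core = np.array([[1, 1, 2], [2, 1, 2], [3, 3, 3]]).reshape(3, 3, 1)
        q = quantized_from_levels(embedded(core), 4)
        mat, f = compute_glszm(q)
        assert mat.sum() == 4  # level-1 x1, level-2 x2, level-3 x1
        assert f["GLSZM_ZP"] == pytest.approx(4 / 9)
        assert mat[0, 2] == 1 and mat[1, 0] == 1 and mat[1, 1] == 1 and mat[2, 2] == 1

    def test_conservation(self, rng):
        from conftest import random_quantized

        for _ in range(50):
            q = random_quantized(rng, shape=(5, 5, 5), n_levels=6)
            mat, _ = compute_glszm(q)
            sizes = np.arange(1, mat.shape[1] + 1)
            assert (mat * sizes).sum() == q.n_voxels


class TestCooccurrence:
    def test_constant_voi(self):
        q = quantized_from_levels(embedded(np.full((2, 2, 2), 1)).astype(int), 4)
        _, f = compute_nglcm(q)
        assert f["NGLCM_ENTROPY"] == 0.0
        assert f["NGLCM_ENERGY"] == 1.0
        _, g = compute_glcm(q)
        assert g["GLCM_CONTRAST"] == 0.0
        assert g["GLCM_HOMOGENEITY"] == 1.0

    def test_two_voxel_pair(self):
        core = np.array([[[1, 2]]])
        q = quantized_from_levels(embedded(core), 2)
        p, f = compute_nglcm(q)
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)
        assert f["NGLCM_ENTROPY"] == pytest.approx(1.0)

    def test_glcm_nglcm_shared_accumulation(self, rng):
        from conftest import random_quantized

        q = random_quantized(rng, shape=(4, 4, 4), n_levels=4)
        _, glcm_f = compute_glcm(q)
        _, nglcm_f = compute_nglcm(q)
        for name in ("ENTROPY", "ENERGY", "CONTRAST", "HOMOGENEITY", "CORRELATION"):
            assert glcm_f[f"GLCM_{name}"] == pytest.approx(nglcm_f[f"NGLCM_{name}"])

    def test_nglcm_entropy_zero_iff_constant(self, rng):
        from conftest import random_quantized

        for _ in range(30):
            q = random_quantized(rng, shape=(3, 3, 3), n_levels=3)
            lv = q.levels[q.mask]
            if q.n_voxels < 2:
                continue
            try:
                _, f = compute_nglcm(q)
            except ValueError:
                continue  # no neighbouring pair
            if len(np.unique(lv)) == 1:
                assert f["NGLCM_ENTROPY"] == 0.0


class TestNGTDM:
    def test_constant_voi(self):
        q = quantized_from_levels(embedded(np.full((2, 2, 2), 2)).astype(int), 4)
        _, f = compute_ngtdm(q)
        assert f["NGTDM_COARSENESS"] == COARSENESS_CAP
        assert f["NGTDM_CONTRAST"] == 0.0

    def test_three_voxel_rod_by_hand(self):
        core = np.array([[[1, 2, 1]]])
        q = quantized_from_levels(embedded(core), 2)
        table, f = compute_ngtdm(q)
        np.testing.assert_array_equal(table.n, [2, 1])
        np.testing.assert_allclose(table.s, [2.0, 1.0])
        # hand-derived Amadasun-King values for this table
        assert f["NGTDM_COARSENESS"] == pytest.approx(3 / 5)
        assert f["NGTDM_CONTRAST"] == pytest.approx(2 / 9)
        assert f["NGTDM_BUSYNESS"] == 0.0  # |1*p1 - 2*p2| = 0
        assert f["NGTDM_COMPLEXITY"] == pytest.approx(10 / 9)
        assert f["NGTDM_STRENGTH"] == pytest.approx(2 / 3)

    def test_occurrence_conservation(self, rng):
        from conftest import random_quantized

        for _ in range(20):
            q = random_quantized(rng, shape=(4, 4, 4), n_levels=4)
            table = ngtdm_table(q)
            # voxels with >= 1 in-mask neighbour
            from oracles import oracle_ngtdm

            n, _ = oracle_ngtdm(q.levels, q.n_levels)
            assert table.n.sum() == n.sum()


class TestNGLDM:
    def test_constant_cube_dependences(self):
        q = quantized_from_levels(embedded(np.full((3, 3, 3), 1)).astype(int), 2)
        mat, _ = compute_ngldm(q)
        assert mat[0, 26] == 1  # centre voxel: 26 identical neighbours
        assert mat[0, 7] == 8  # corners: 7 identical neighbours

    def test_all_distinct_minimal_dependence(self):
        core = np.array([[[1], [2]], [[3], [4]]])
        q = quantized_from_levels(embedded(core), 4)
        mat, f = compute_ngldm(q)
        assert mat[:, 0].sum() == 4  # every voxel dependence 0
        assert f["NGLDM_SNE"] == pytest.approx(1.0)
        assert f["NGLDM_LNE"] == pytest.approx(1.0)


class TestExtract:
    def test_roster_and_determinism(self, rng):
        core = rng.random((5, 5, 4)) * 10 + 1
        vol, mask = box_voi(core)
        f1 = extract_features(vol, mask)
        f2 = extract_features(vol, mask)
        assert tuple(f1) == FEATURE_NAMES
        assert len(f1) == 44
        assert f1 == f2
        assert all(np.isfinite(v) for v in f1.values())

    def test_rotation_invariance_in_plane(self, rng):
        # 90-degree rotation about z keeps the (equal) in-plane spacings,
        # so every feature must be unchanged
        core = rng.random((5, 5, 4)) * 10 + 1
        vol, mask = box_voi(core)
        rot_vals = np.rot90(vol.values, k=1, axes=(0, 1)).copy()
        rot_mask = np.rot90(mask.mask, k=1, axes=(0, 1)).copy()
        f = extract_features(vol, mask)
        g = extract_features(make_volume(rot_vals), make_mask(rot_mask))
        for name in FEATURE_NAMES:
            assert g[name] == pytest.approx(f[name], rel=1e-9), name

    def test_axis_permutation_invariance_texture(self, rng):
        # texture/histogram features are index-order agnostic; axis swap with
        # anisotropic spacing must leave them unchanged
        core = rng.random((4, 5, 6)) * 8 + 1
        vol, mask = box_voi(core)
        f = extract_features(vol, mask)
        swapped = make_volume(vol.values.transpose(1, 0, 2), SPACING)
        mask_s = make_mask(mask.mask.transpose(1, 0, 2), SPACING)
        g = extract_features(swapped, mask_s)
        for name in FEATURE_NAMES:
            if name.split("_")[0] in ("GLCM", "NGLCM", "GLSZM", "NGTDM", "NGLDM", "HIST") or name in (
                "SUVmax", "SUVmean", "MTV", "TLG"
            ):
                assert g[name] == pytest.approx(f[name], rel=1e-9), name
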