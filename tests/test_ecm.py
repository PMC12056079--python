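"""Tests of eigenvector centrality mapping and cluster-level inference."""

import numpy as np
import pytest
from scipy import stats

from fcpair.ecm import (
    VoxelGrid,
    cluster_level_test,
    compute_ec,
    correlate_delta_ec_with_clinical,
    correlate_scores,
    coverage_threshold,
    delta_ec,
    extract_clusters,
    smooth_grid,
    voxelwise_one_sample_t,
)


class TestSmoothGrid:
    def test_impulse_matches_analytic_gaussian(self):
        shape = (21, 21, 21)
        n = np.prod(shape)
        data = np.zeros((1, n))
        centre = np.ravel_multi_index((10, 10, 10), shape)
        data[0, centre] = 1.0
        fwhm, vox = 5.0, 3.0
        out = smooth_grid(data, shape, fwhm_mm=fwhm, voxel_size_mm=vox)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        grid = np.indices(shape).reshape(3, -1)
        d2 = ((grid - 10.0) ** 2).sum(axis=0)
        analytic = np.exp(-d2 / (2 * sigma**2))
        analytic /= analytic.sum()
        inner = d2 <= 4  # near the impulse, away from kernel truncation
        np.testing.assert_allclose(
            out[0, inner], analytic[inner], rtol=0.01, atol=1e-5
        )

    def test_constant_field_unchanged_in_mask(self):
        shape = (8, 8, 8)
        n = np.prod(shape)
        coverage = np.ones(n, bool)
        coverage[: n // 3] = False
        data = np.full((2, n), 3.5)
        out = smooth_grid(data, shape, coverage)
        np.testing.assert_allclose(out[:, coverage], 3.5, atol=1e-10)

    def test_fwhm_zero_is_identity(self, rng):
        data = rng.standard_normal((3, 64))
        out = smooth_grid(data, (4, 4, 4), fwhm_mm=0.0)
        np.testing.assert_array_equal(out, data)


class TestComputeEC:
    def test_equicorrelated_voxels_uniform_ec(self, rng):
        # one shared signal plus microscopic noise: every |r| is equal
        n = 30
        common = rng.standard_normal((100, 1))
        series = common + 1e-6 * rng.standard_normal((100, n))
        ec = compute_ec(series).ec
        np.testing.assert_allclose(ec, 1.0 / np.sqrt(n), atol=1e-4)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        series = rng.standard_normal((120, 50))
        ec = compute_ec(series).ec
        a = np.abs(np.corrcoef(series, rowvar=False))
        w, v = np.linalg.eigh(a)
        lead = np.abs(v[:, -1])
        lead /= np.linalg.norm(lead)
        assert np.abs(ec - lead).max() < 1e-8

    def test_stronger_block_dominates(self, rng):
        # two internally coherent blocks with no cross-talk: EC mass
        # concentrates on the block with higher internal correlation
        t = 4000
        s1 = rng.standard_normal((t, 1))
        s2 = rng.standard_normal((t, 1))
        block1 = 0.9 * s1 + 0.1 * rng.standard_normal((t, 10))
        block2 = 0.4 * s2 + 0.9 * rng.standard_normal((t, 10))
        series = np.column_stack([block1, block2])
        ec = compute_ec(series).ec
        assert ec[:10].sum() > 5 * ec[10:].sum()

    def test_chunked_equals_dense(self, rng):
        series = rng.standard_normal((60, 40))
        dense = compute_ec(series, dense_voxel_limit=1000).ec
        chunked = compute_ec(series, dense_voxel_limit=0, chunk_rows=7).ec
        np.testing.assert_allclose(chunked, dense, atol=1e-9)

    def test_scale_invariance(self, rng):
        series = rng.standard_normal((80, 20))
        a = compute_ec(series).ec
        b = compute_ec(series * 37.5).ec
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_voxel_reordering_permutes_ec(self, rng):
        series = rng.standard_normal((90, 15))
        perm = rng.permutation(15)
        a = compute_ec(series).ec
        b = compute_ec(series[:, perm]).ec
        np.testing.assert_allclose(b, a[perm], atol=1e-9)

    def test_zero_variance_voxels_excluded_with_warning(self, rng):
        series = rng.standard_normal((50, 10))
        series[:, 3] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            ecmap = compute_ec(series)
        assert np.isnan(ecmap.ec[3])
        assert 3 in ecmap.excluded_voxels
        assert np.linalg.norm(ecmap.ec[~np.isnan(ecmap.ec)]) == pytest.approx(1.0)

    def test_coverage_respected(self, rng):
        series = rng.standard_normal((50, 12))
        cov = np.ones(12, bool)
        cov[[0, 5]] = False
        ec = compute_ec(series, coverage=cov).ec
        assert np.isnan(ec[0]) and np.isnan(ec[5])
        assert np.isfinite(ec[cov]).all()

    def test_unit_norm_and_nonnegative(self, rng):
        ec = compute_ec(rng.standard_normal((70, 25))).ec
        assert (ec >= 0).all()
        assert np.linalg.norm(ec) == pytest.approx(1.0)


class TestDeltaAndCoverage:
    def test_identical_maps_zero(self, rng):
        ec = rng.random(10)
        np.testing.assert_allclose(delta_ec(ec, ec), 0.0)

    def test_hand_three_voxel_case(self):
        d = delta_ec(np.array([0.5, 0.3, 0.2]), np.array([0.1, 0.4, 0.2]))
        np.testing.assert_allclose(d, [0.4, -0.1, 0.0])

    def test_one_sided_coverage_marks_missing(self):
        d = delta_ec(np.array([0.5, np.nan]), np.array([0.2, 0.3]))
        assert np.isnan(d[1]) and d[0] == pytest.approx(0.3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_ec(np.zeros(3), np.zeros(4))

    def test_coverage_threshold_rules(self):
        maps = np.ones((29, 4))
        maps[:15, 0] = np.nan  # 14 subjects cover voxel 0
        maps[:14, 1] = np.nan  # 15 subjects cover voxel 1
        mask = coverage_threshold(maps, min_participants=15)
        assert not mask[0]
        assert mask[1]
        full = coverage_threshold(np.ones((29, 4)), min_participants=29)
        assert full.all()


class TestVoxelwiseT:
    def test_null_calibration_at_p005(self, rng):
        maps = rng.standard_normal((29, 10000))
        mask = np.ones(10000, bool)
        t, p, _ = voxelwise_one_sample_t(maps, mask)
        rate = np.mean(p <= 0.005)
        assert 0.003 <= rate <= 0.007

    def test_constant_positive_shift_detected(self, rng):
        maps = 0.5 + 0.01 * rng.standard_normal((20, 5))
        t, p, _ = voxelwise_one_sample_t(maps, np.ones(5, bool))
        assert (t > 0).all()
        assert (p < 1e-10).all()

    def test_zero_variance_flagged(self):
        maps = np.zeros((10, 2))
        maps[:, 1] = np.arange(10.0)
        t, p, flags = voxelwise_one_sample_t(maps, np.ones(2, bool))
        assert flags[0] and p[0] == 1.0

    def test_insufficient_coverage_excluded(self):
        maps = np.full((10, 1), np.nan)
        maps[:2, 0] = 1.0
        t, p, _ = voxelwise_one_sample_t(maps, np.ones(1, bool))
        assert np.isnan(t[0]) and np.isnan(p[0])

    def test_matches_scipy_on_complete_data(self, rng):
        maps = rng.standard_normal((15, 30)) + 0.2
        t, p, _ = voxelwise_one_sample_t(maps, np.ones(30, bool))
        t_ref, p_ref = stats.ttest_1samp(maps, 0.0, axis=0)
        np.testing.assert_allclose(t, t_ref, atol=1e-10)
        np.testing.assert_allclose(p, p_ref, atol=1e-12)


def flood_fill_clusters(supra, shape, connectivity=26):
    """Brute-force BFS connected components (independent oracle)."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                manh = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and manh > 1:
                    continue
                if connectivity == 18 and manh > 2:
                    continue
                offsets.append((di, dj, dk))
    vol = supra.reshape(shape)
    seen = np.zeros(shape, bool)
    comps = []
    for idx in np.argwhere(vol):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack, comp = [idx], []
        seen[idx] = True
        while stack:
            cur = stack.pop()
            comp.append(np.ravel_multi_index(cur, shape))
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[d] < shape[d] for d in range(3)) and vol[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


class TestExtractClusters:
    def test_empty_suprathreshold_set(self):
        shape = (5, 5, 5)
        n = 125
        out = extract_clusters(np.ones(n), np.ones(n), np.ones(n, bool), shape)
        assert out == []

    def test_strict_size_threshold_excludes_exactly_min_size(self):
        shape = (10, 4, 4)
        n = 160
        p = np.ones(n)
        t = np.zeros(n)
        vol_idx = [np.ravel_multi_index((i, 0, 0), shape) for i in range(10)]
        for i in vol_idx:
            p[i] = 0.001
            t[i] = 2.0
        mask = np.ones(n, bool)
        assert extract_clusters(p, t, mask, shape, min_size=10) == []
        out = extract_clusters(p, t, mask, shape, min_size=10, strict_size=False)
        assert len(out) == 1 and out[0]["size"] == 10

    def test_two_blobs_with_opposite_signs(self):
        shape = (8, 8, 8)
        n = 512
        p = np.ones(n)
        t = np.zeros(n)
        pos = [np.ravel_multi_index((i, j, 0), shape) for i in range(4) for j in range(4)]
        neg = [np.ravel_multi_index((i, j, 7), shape) for i in range(4) for j in range(4)]
        for i in pos:
            p[i], t[i] = 0.001, 3.0
        for i in neg:
            p[i], t[i] = 0.001, -3.0
        out = extract_clusters(p, t, np.ones(n, bool), shape, min_size=10)
        assert len(out) == 2
        dirs = {c["direction"] for c in out}
        assert dirs == {"positive", "negative"}
        for c in out:
            assert c["size"] == 16

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_grids(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 9, size=3))
        n = int(np.prod(shape))
        p = rng.uniform(size=n)
        t = np.abs(rng.standard_normal(n))  # one sign: clusters = components
        mask = rng.random(n) < 0.9
        supra = mask & (p <= 0.3)
        expected = [
            c for c in flood_fill_clusters(supra, shape, connectivity) if len(c) > 2
        ]
        got = extract_clusters(
            p, t, mask, shape, p_thresh=0.3, min_size=2, connectivity=connectivity
        )
        got_sets = sorted(sorted(c["voxels"].tolist()) for c in got)
        assert got_sets == sorted(expected)

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError):
            extract_clusters(np.ones(8), np.ones(8), np.ones(8, bool), (2, 2, 2),
                             connectivity=10)


class TestClusterLevel:
    def test_single_cluster_adjusted_equals_raw(self, rng):
        maps = rng.standard_normal((12, 27)) + 0.8
        clusters = [{"voxels": np.arange(5), "size": 5, "direction": "positive"}]
        table = cluster_level_test(clusters, maps)
        assert table.loc[0, "p_fdr"] == pytest.approx(table.loc[0, "p_raw"])

    def test_sign_consistency(self, rng):
        maps = rng.standard_normal((15, 20)) * 0.1 - 0.5
        clusters = [{"voxels": np.arange(8), "size": 8, "direction": "negative"}]
        table = cluster_level_test(clusters, maps)
        assert np.sign(table.loc[0, "t"]) == np.sign(table.loc[0, "mean_delta_ec"])
        assert table.loc[0, "t"] < 0

    def test_empty_cluster_list(self):
        table = cluster_level_test([], np.zeros((5, 4)))
        assert len(table) == 0
        assert "p_fdr" in table.columns


class TestClinicalCorrelation:
    def test_score_equal_to_voxel_delta_gives_r_one(self, rng):
        maps = rng.standard_normal((20, 30))
        score = maps[:, 7].copy()
        r_map, p_map = (
            correlate_delta_ec_with_clinical(
                maps, score, np.ones(30, bool), (5, 3, 2)
            )[:2]
        )
        assert r_map[7] == pytest.approx(1.0)

    def test_null_calibration_voxelwise(self, rng):
        maps = rng.standard_normal((29, 8000))
        score = rng.standard_normal(29)
        r_map, p_map, _ = correlate_delta_ec_with_clinical(
            maps, score, np.ones(8000, bool), (20, 20, 20)
        )
        rate = np.mean(p_map <= 0.005)
        assert 0.003 <= rate <= 0.007

    def test_constant_score_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            correlate_delta_ec_with_clinical(
                rng.standard_normal((10, 8)), np.ones(10), np.ones(8, bool),
                (2, 2, 2)
            )


class TestCorrelateScores:
    def test_identical_vectors(self):
        r, p = correlate_scores([1.0, 2, 3, 5], [1.0, 2, 3, 5])
        assert r == pytest.approx(1.0)

    def test_orthogonal_centred_pair(self):
        a = np.array([-1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, -1.0, 0.0, 1.0])
        r, _ = correlate_scores(a, b)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.standard_normal(29), rng.standard_normal(29)
        r, p = correlate_scores(a, b)
        am, bm = a - a.mean(), b - b.mean()
        r_ref = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            correlate_scores([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestVoxelGrid:
    def test_size_checks(self):
        with pytest.raises(ValueError):
            VoxelGrid(shape=(2, 2, 2), coverage=np.ones(7, bool),
                      parcels=np.zeros(8, int))


class TestNiftiExport:
    def test_roundtrip_map(self, tmp_path, rng):
        import nibabel as nib

        from fcpair.ecm import export_nifti

        shape = (4, 5, 6)
        values = rng.standard_normal(120)
        path = tmp_path / "map.nii.gz"
        export_nifti(values, shape, path)
        img = nib.load(str(path))
        np.testing.assert_allclose(
            np.asarray(img.dataobj).ravel(), values, rtol=1e-6
        )
        assert img.affine[0, 0] == 3.0
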