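"""Ratemaps, remapping measures, spatial information, PCA, Ripley/KDE."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from placenet import analysis as an
from placenet.geometry import make_environment, sample_uniform
from placenet.network import init_params


class TestRatemap:
    def test_constant_activity_gives_constant_map(self, square, rng):
        pts = sample_uniform(square, 4000, rng)
        rm = an.compute_ratemap(np.ones(4000), pts, square, bins=8)
        assert np.allclose(rm.grid[rm.visited], 1.0)

    def test_bin_mean(self, square):
        pos = np.array([[0.01, 0.01], [0.02, 0.02]])
        rm = an.compute_ratemap(np.array([1.0, 3.0]), pos, square, bins=4)
        assert rm.grid[rm.visited].tolist() == [2.0]

    def test_unvisited_bins_are_nan_not_zero(self, square):
        pos = np.array([[0.01, 0.01], [0.02, 0.02]])
        rm = an.compute_ratemap(np.array([1.0, 1.0]), pos, square, bins=4)
        assert np.isnan(rm.grid).sum() == 15

    def test_burn_in_discards_prefix(self, square):
        pos = np.tile([[0.0, 0.0]], (10, 1))
        act = np.array([100.0] * 5 + [1.0] * 5)
        rm = an.compute_ratemap(act, pos, square, bins=2, burn_in=5)
        assert rm.grid[rm.visited].tolist() == [1.0]

    def test_empty_after_burn_in_raises(self, square):
        with pytest.raises(ValueError, match="burn-in"):
            an.compute_ratemap(np.ones(3), np.zeros((3, 2)), square, burn_in=3)

    def test_misaligned_inputs_raise(self, square):
        with pytest.raises(ValueError, match="aligned"):
            an.compute_ratemap(np.ones(4), np.zeros((3, 2)), square)


class TestSmoothing:
    def test_uniform_map_unchanged(self):
        grid = np.full((16, 16), 3.5)
        np.testing.assert_allclose(an.smooth_grid(grid), grid, atol=1e-12)

    def test_single_nan_filled_with_uniform_value(self):
        grid = np.full((16, 16), 2.0)
        grid[7, 7] = np.nan
        out = an.smooth_grid(grid)
        assert out[7, 7] == pytest.approx(2.0, abs=1e-10)

    def test_impulse_matches_renormalized_kernel_oracle(self):
        # brute-force oracle: explicit truncated Gaussian kernel, renormalized
        # over defined bins only
        rng = np.random.default_rng(0)
        grid = rng.uniform(0, 1, (9, 9))
        grid[rng.uniform(size=(9, 9)) < 0.2] = np.nan
        sigma, radius = 1.0, 4
        ax = np.arange(-radius, radius + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        kern = np.outer(k1, k1)
        expected = np.empty_like(grid)
        for i in range(9):
            for j in range(9):
                num = den = 0.0
                for di in range(-radius, radius + 1):
                    for dj in range(-radius, radius + 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 9 and 0 <= jj < 9 and not np.isnan(grid[ii, jj]):
                            w = kern[di + radius, dj + radius]
                            num += w * grid[ii, jj]
                            den += w
                expected[i, j] = num / den
        np.testing.assert_allclose(an.smooth_grid(grid), expected, atol=1e-10)

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            an.smooth_grid(np.full((4, 4), np.nan))


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self, rng):
        g = rng.uniform(size=(16, 16))
        assert an.spatial_correlation(g, g) == pytest.approx(1.0)

    def test_rotation_search_recovers_rotated_map(self, rng):
        g = rng.uniform(size=(16, 16))
        assert an.spatial_correlation(np.rot90(g), g) == pytest.approx(1.0)

    def test_rotation_0_matches_pearson_oracle(self, rng):
        a = rng.uniform(size=(8, 8))
        b = rng.uniform(size=(8, 8))
        from scipy.stats import pearsonr

        expected = pearsonr(a.ravel(), b.ravel()).statistic
        assert an.spatial_correlation(a, b, try_rotations=False) == pytest.approx(expected)

    def test_too_few_joint_bins_undefined(self):
        a = np.full((4, 4), np.nan)
        a[0, 0] = 1.0
        assert np.isnan(an.spatial_correlation(a, a))

    def test_bounded(self, rng):
        for _ in range(20):
            v = an.spatial_correlation(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)))
            assert -1 <= v <= 1


class TestRateMeasures:
    @pytest.mark.parametrize("a,b,expected", [(3, 3, 1.0), (0, 4, 0.0), (2, 4, 0.5)])
    def test_overlap(self, a, b, expected):
        assert an.rate_overlap(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("a,b,expected", [(4, 2, 1 / 3), (2, 4, -1 / 3), (5, 0, 1.0)])
    def test_difference(self, a, b, expected):
        assert an.rate_difference(a, b) == pytest.approx(expected)

    def test_both_silent_rejected(self):
        with pytest.raises(ValueError):
            an.rate_overlap(0.0, 0.0)
        with pytest.raises(ValueError):
            an.rate_difference(0.0, 0.0)

    def test_shuffled_null_correlation_mode_excludes_matched_pairs(self, rng):
        maps = [rng.uniform(size=(4, 4)) for _ in range(5)]
        null = an.shuffled_null(maps, maps, mode="correlation")
        assert len(null["values"]) <= 5 * 4  # i != j pairs only
        assert np.all((null["values"] >= -1) & (null["values"] <= 1))

    def test_shuffled_null_percentile_is_the_95th_order_statistic(self, rng):
        # rate-overlap null on known values: the reported 95th percentile must
        # match numpy's order statistic of the sampled pairing values
        rates = list(np.arange(1.0, 11.0))
        got = an.shuffled_null(rates, rates, mode="overlap", n_pairings=500, rng=rng)
        assert np.all((got["values"] >= 0) & (got["values"] <= 1))
        assert got["p95"] == pytest.approx(np.percentile(got["values"], 95))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            an.shuffled_null([1], [1], mode="bogus")


class TestPVCorrelation:
    def test_identical_stacks(self, rng):
        s = rng.uniform(size=(5, 8, 8))
        assert an.pv_correlation(s, s) == pytest.approx(1.0)

    def test_negated_stack(self, rng):
        s = rng.uniform(size=(5, 8, 8))
        assert an.pv_correlation(s, -s) == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self, rng):
        from scipy.stats import pearsonr

        a, b = rng.normal(size=(3, 4, 4)), rng.normal(size=(3, 4, 4))
        assert an.pv_correlation(a, b) == pytest.approx(pearsonr(a.ravel(), b.ravel()).statistic)

    def test_time_matrix_diagonal_one(self, square, rng):
        n, T, U = 300, 6, 4
        X = sample_uniform(square, n * T, rng).reshape(n, T, 2)
        P = rng.uniform(0, 1, (n, T, U)) * (1 + X[..., :1])  # spatially modulated
        M = an.pv_time_correlation(P, X, square, bins=8)
        np.testing.assert_allclose(np.diag(M), 1.0, atol=1e-10)
        assert np.all(M <= 1 + 1e-9)


class TestSpatialInformation:
    def test_uniform_map_zero_bits(self, square, rng):
        pts = sample_uniform(square, 5000, rng)
        rm = an.compute_ratemap(np.ones(5000), pts, square, bins=4)
        assert an.spatial_information(rm) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bins", [2, 4])
    def test_one_hot_map_log2_M(self, square, bins):
        # every bin equally occupied, all rate in one bin -> log2(M) bits
        cx = np.linspace(-1.0, 1.0, bins)
        pos = np.array([[x, y] for x in cx for y in cx])
        act = np.zeros(len(pos))
        act[0] = 5.0
        rm = an.compute_ratemap(act, pos, square, bins=bins)
        assert an.spatial_information(rm) == pytest.approx(np.log2(bins**2), abs=1e-10)

    def test_silent_map_zero(self, square):
        rm = an.compute_ratemap(np.zeros(10), np.zeros((10, 2)), square, bins=2)
        assert an.spatial_information(rm) == 0.0

    def test_nonnegative(self, square, rng):
        pts = sample_uniform(square, 2000, rng)
        rm = an.compute_ratemap(rng.uniform(0, 2, 2000), pts, square, bins=8)
        assert an.spatial_information(rm) >= 0.0


class TestHighSIUnits:
    def test_percentile_zero_keeps_all_defined(self):
        si = np.array([[1.0, 2.0], [np.nan, 1.0], [0.5, 3.0]])
        assert an.high_si_units(si, percentile=0).tolist() == [0, 2]

    def test_single_env_median_keeps_upper_half(self, rng):
        si = np.arange(10, dtype=float)[:, None]
        kept = an.high_si_units(si, percentile=50)
        assert kept.tolist() == [5, 6, 7, 8, 9]

    def test_intersection_over_environments(self):
        si = np.array([[9.0, 0.1], [9.0, 9.0], [0.1, 9.0]])
        kept = an.high_si_units(si, percentile=25)
        assert kept.tolist() == [1]


class TestPCA:
    def test_rank_one_data(self, rng):
        u = rng.normal(size=(100, 1)) @ rng.normal(size=(1, 7))
        out = an.pca_spectrum(u)
        assert out["fractions"][0] == pytest.approx(1.0)

    def test_isotropic_data_flat_spectrum(self, rng):
        d = 5
        out = an.pca_spectrum(rng.normal(size=(20000, d)))
        np.testing.assert_allclose(out["fractions"], 1 / d, atol=0.02)

    def test_cumulative_monotone_ends_at_one(self, rng):
        out = an.pca_spectrum(rng.normal(size=(50, 6)))
        assert np.all(np.diff(out["cumulative"]) >= -1e-12)
        assert out["cumulative"][-1] == pytest.approx(1.0)
        assert 1 <= out["n_components"] <= 6


class TestWeightDiagnostics:
    def test_fresh_identity_spectrum(self, rng):
        p = init_params(12, 4, rng=rng)
        d = an.weight_diagnostics(p)
        np.testing.assert_allclose(d["eigenvalues"], np.ones(12), atol=1e-6)
        np.testing.assert_allclose(np.diag(d["context_correlations"]), 1.0, atol=1e-12)
        assert d["context_negative_fraction"].shape == (6,)

    def test_eigenvalues_match_characteristic_polynomial_roots(self):
        W = np.array([[2.0, 1.0, 0, 0], [0, 3.0, 1.0, 0], [0, 0, 5.0, 0], [1.0, 0, 0, 7.0]])
        p = init_params(4, 2, rng=np.random.default_rng(0), dtype=np.float64)
        p.W_R = W
        got = np.sort_complex(an.weight_diagnostics(p)["eigenvalues"])
        coeffs = np.poly(W)
        expected = np.sort_complex(np.roots(coeffs))
        np.testing.assert_allclose(got, expected, atol=1e-8)


class TestRipley:
    def test_two_distant_points_zero_K(self):
        pts = np.array([[10.0, 10.0], [60.0, 60.0]])
        K = an.ripleys_K(pts, [[0, 0], [75, 75]], radii=np.array([1.0, 5.0]))
        assert (K == 0).all()

    def test_interior_configuration_matches_uncorrected_bruteforce(self, rng):
        # points clustered mid-domain with radii smaller than the distance to
        # any wall: every correction factor is exactly 1
        pts = rng.uniform(30, 45, size=(25, 2))
        domain = [[0, 0], [75, 75]]
        radii = np.geomspace(1e-8, 10.0, 20)
        K = an.ripleys_K(pts, domain, radii)
        N = len(pts)
        brute = []
        for R in radii:
            c = sum(
                1
                for i in range(N)
                for j in range(N)
                if i != j and np.linalg.norm(pts[i] - pts[j]) < R
            )
            brute.append(75 * 75 / (N * (N - 1)) * c)
        np.testing.assert_allclose(K, brute, atol=1e-9)

    def test_K_monotone_nondecreasing(self, rng):
        pts = rng.uniform(0, 75, size=(40, 2))
        K = an.ripleys_K(pts, [[0, 0], [75, 75]], an.default_radii([[0, 0], [75, 75]]))
        assert np.all(np.diff(K) >= -1e-12)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            an.ripleys_K(np.array([[1.0, 1.0]]), [[0, 0], [5, 5]])

    def test_H_closed_form(self):
        radii = np.linspace(0.1, 5, 9)
        np.testing.assert_allclose(an.ripleys_H(np.pi * radii**2, radii), 0.0, atol=1e-12)

    def test_default_radii_span(self):
        r = an.default_radii([[0, 0], [75, 75]])
        assert len(r) == 50
        assert r[0] == pytest.approx(1e-8)
        assert r[-1] == pytest.approx(75 * np.sqrt(2) / 4)

    def test_edge_correction_matches_shapely_oracle(self, rng):
        env = make_environment("square")
        pts = sample_uniform(env, 12, rng)
        radii = np.array([0.3, 0.8])
        K_mine = an.ripleys_K(pts, env, radii)
        poly = Polygon([tuple(s[0]) for s in env.outer_walls])
        iu, ju = np.triu_indices(len(pts), k=1)
        K_ref = []
        for R in radii:
            tot = 0.0
            for i, j in zip(iu, ju):
                d = np.linalg.norm(pts[i] - pts[j])
                if d < R:
                    f = 0.0
                    for a in (i, j):
                        ring = Point(pts[a]).buffer(d, quad_segs=512).exterior
                        f += 0.5 * ring.length / ring.intersection(poly).length
                    tot += 2 * f
            K_ref.append(env.area / (len(pts) * (len(pts) - 1)) * tot)
        np.testing.assert_allclose(K_mine, K_ref, rtol=0.02)


class TestFieldCentersAndKDE:
    def test_single_peak_center(self):
        g = np.zeros((15, 15))
        g[4, 9] = 2.0
        ex = np.linspace(0, 75, 16)
        centers = an.field_centers_from_ratemaps(g[None], ex, ex)
        cx = 0.5 * (ex[:-1] + ex[1:])
        np.testing.assert_allclose(centers[0], [cx[4], cx[9]])

    def test_si_percentile_filter(self, rng):
        grids = rng.uniform(size=(8, 15, 15))
        ex = np.linspace(0, 75, 16)
        si = np.arange(8, dtype=float)
        kept = an.field_centers_from_ratemaps(grids, ex, ex, si=si, si_percentile=75)
        assert len(kept) == 2  # only units strictly above the 75th percentile

    def test_kde_peak_at_single_point(self):
        res = an.kde(np.array([[30.0, 40.0]]), [[0, 0], [75, 75]], bandwidth=2.0)
        ix, iy = np.unravel_index(np.argmax(res["density"]), res["density"].shape)
        assert abs(res["x"][ix] - 30) < 1.5 and abs(res["y"][iy] - 40) < 1.5

    def test_kde_normalization_quadrature(self, rng):
        pts = rng.uniform(25, 50, size=(40, 2))
        res = an.kde(pts, [[0, 0], [75, 75]], bandwidth=0.2 * 75 / 2.2, grid=128)
        cell = (res["x"][1] - res["x"][0]) * (res["y"][1] - res["y"][0])
        assert res["density"].sum() * cell == pytest.approx(1.0, abs=0.02)


class TestDecodedCenterAggregation:
    def test_cloud_shapes_and_dispersion(self, rng):
        # an untrained network still yields per-trajectory center estimates;
        # clouds must have one entry per trajectory per kept unit
        p = init_params(16, 6, rng=rng)
        env = make_environment("square")
        clouds = an.decoded_center_aggregation(p, env, n_traj=4, T=300, rng=rng,
                                               unit_subset=np.array([0, 2]))
        assert clouds.shape == (2, 4, 2)
        assert np.isfinite(clouds).all()
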