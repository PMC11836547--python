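"""Hypervolume dissimilarity, PCA projection, bias correction, novelty."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from paleoshift.climate_space import (
    FEATURE_COLUMNS,
    bias_correct,
    bootstrap_hypervolume,
    dissimilarity,
    mahalanobis_novelty,
    overlap_sorensen,
    pca_reference,
    seasonal_features,
)


class TestSeasonalFeatures:
    def test_one_row_per_cell_year(self, tiny_climate):
        slc = tiny_climate[0]
        df = seasonal_features(slc)
        ny = slc.seasonal_tmean.shape[0]
        assert len(df) == ny * slc.shape[0] * slc.shape[1]
        assert list(df.columns[:-1]) == list(FEATURE_COLUMNS)

    def test_constant_climate_gives_identical_rows(self, tiny_landscape):
        from paleoshift.synthetic_world import ClimateTrajectory, gen_climate_series

        traj = ClimateTrajectory(start_bp=12_000, end_bp=11_750, noise_sd=0.0)
        slc = gen_climate_series(
            type(tiny_landscape)(n_rows=2, n_cols=2, seed=0), traj)[0]
        # zero out the spatial gradients by slicing a single cell
        df = seasonal_features(slc)
        one_cell = df.iloc[0::4]  # same cell across years
        assert np.allclose(one_cell[list(FEATURE_COLUMNS)].std(), 0.0)

    def test_matches_hand_assembled_fixture(self, tiny_climate):
        slc = tiny_climate[0]
        df = seasonal_features(slc)
        # row order is (year, row, col); check an arbitrary entry
        ny, _, nr, nc = slc.seasonal_tmean.shape
        year, r, c = 3, 2, 5
        row = df.iloc[year * nr * nc + r * nc + c]
        for s in range(4):
            assert row[f"tmean_q{s+1}"] == slc.seasonal_tmean[year, s, r, c]
            assert row[f"prec_q{s+1}"] == slc.seasonal_prec[year, s, r, c]


class TestBiasCorrect:
    def test_identity_when_reference_matches(self, tiny_climate):
        ref = tiny_climate[-1]
        out = bias_correct(tiny_climate, ref, ref)
        assert np.allclose(out[0].seasonal_tmean, tiny_climate[0].seasonal_tmean)
        assert np.allclose(out[0].seasonal_prec, tiny_climate[0].seasonal_prec)

    def test_constant_temperature_bias_removed(self, tiny_climate):
        import copy

        ref = tiny_climate[-1]
        biased_ref = copy.copy(ref)
        biased_ref.seasonal_tmean = ref.seasonal_tmean + 2.0
        biased = [copy.copy(s) for s in tiny_climate]
        for s in biased:
            s.seasonal_tmean = s.seasonal_tmean + 2.0
        out = bias_correct(biased, biased_ref, ref)
        assert np.allclose(out[0].seasonal_tmean, tiny_climate[0].seasonal_tmean,
                           atol=1e-10)

    def test_precipitation_ratio_rule(self, tiny_climate):
        import copy

        ref = tiny_climate[-1]
        sim_ref = copy.copy(ref)
        sim_ref.seasonal_prec = np.full_like(ref.seasonal_prec, 50.0)
        obs_ref = copy.copy(ref)
        obs_ref.seasonal_prec = np.full_like(ref.seasonal_prec, 100.0)
        series = [copy.copy(ref)]
        series[0].seasonal_prec = np.full_like(ref.seasonal_prec, 30.0)
        out = bias_correct(series, sim_ref, obs_ref)
        assert np.allclose(out[0].seasonal_prec, 60.0)


class TestPcaReference:
    def test_isotropic_projection_preserves_distances(self, rng):
        X = rng.normal(size=(400, 3))
        cols = list(FEATURE_COLUMNS)[:3]
        # embed the 3-D cloud in the 8-feature layout with constant padding
        full = np.hstack([X, np.ones((400, 5)) + rng.normal(0, 1, (400, 5))])
        proj = pca_reference(full, k=3)
        # identical rows map to identical coordinates
        Z1 = proj.transform(full)
        Z2 = proj.transform(full.copy())
        assert np.allclose(Z1, Z2)

    def test_dominant_axis_explains_variance(self, rng):
        # one latent factor drives every (standardised) feature
        base = rng.normal(size=(300, 1))
        X = base @ np.ones((1, 8)) * [3, 1, -2, 0.5, 4, -1, 2, 1.5] \
            + rng.normal(0, 0.01, (300, 8))
        proj = pca_reference(X, k=3)
        assert proj.explained_variance_ratio[0] > 0.99

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            pca_reference(np.ones((50, 8)), k=3)


class TestBootstrapHypervolume:
    def test_identical_points_rejected(self, rng):
        pts = np.ones((100, 3))
        with pytest.raises(ValueError):
            bootstrap_hypervolume(pts, n_boot=2, rng=rng)

    def test_reproducible_with_seed(self):
        pts = np.random.default_rng(0).normal(size=(200, 3))
        a = bootstrap_hypervolume(pts, n_boot=1, rng=np.random.default_rng(4),
                                  cloud_size=300)
        b = bootstrap_hypervolume(pts, n_boot=1, rng=np.random.default_rng(4),
                                  cloud_size=300)
        assert np.array_equal(a[0].points, b[0].points)
        assert a[0].volume == b[0].volume

    def test_volume_close_to_analytic_gaussian_region(self):
        """For a 3-D standard normal, the 95% density region is a ball of
        radius sqrt(chi2_{3,0.95}); the KDE region volume should land within
        15% of its volume."""
        from scipy.stats import chi2

        pts = np.random.default_rng(11).normal(size=(1000, 3))
        hvs = bootstrap_hypervolume(pts, n_boot=4, rng=np.random.default_rng(2),
                                    cloud_size=2000)
        analytic = 4.0 / 3.0 * np.pi * chi2.ppf(0.95, df=3) ** 1.5
        mean_vol = np.mean([h.volume for h in hvs])
        assert mean_vol == pytest.approx(analytic, rel=0.15)


class TestOverlap:
    @staticmethod
    def _hv(points, seed, cloud=1500):
        return bootstrap_hypervolume(points, n_boot=1,
                                     rng=np.random.default_rng(seed),
                                     cloud_size=cloud)[0]

    def test_self_overlap_is_one(self):
        pts = np.random.default_rng(0).normal(size=(500, 3))
        hv = self._hv(pts, 1)
        assert overlap_sorensen(hv, hv) == pytest.approx(1.0, abs=0.05)

    def test_disjoint_clouds_overlap_zero(self):
        rng = np.random.default_rng(0)
        a = self._hv(rng.normal(size=(400, 3)), 1)
        b = self._hv(rng.normal(size=(400, 3)) + 30.0, 2)
        assert overlap_sorensen(a, b) == pytest.approx(0.0, abs=0.01)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a = self._hv(rng.normal(size=(300, 3)), 1)
        b_pts = rng.normal(size=(300, 2))
        b = bootstrap_hypervolume(b_pts, n_boot=1, rng=np.random.default_rng(2),
                                  cloud_size=500)[0]
        with pytest.raises(ValueError):
            overlap_sorensen(a, b)

    def test_shifted_normals_match_monte_carlo_oracle(self):
        """delta=1 shifted unit normals: the cloud-based Sorensen overlap of
        the two KDE regions agrees with a direct Monte-Carlo volume
        integration of the same regions."""
        rng = np.random.default_rng(3)
        A = rng.normal(size=(800, 3))
        B = rng.normal(size=(800, 3)) + np.array([1.0, 0.0, 0.0])
        hva = self._hv(A, 10, cloud=2500)
        hvb = self._hv(B, 11, cloud=2500)
        measured = overlap_sorensen(hva, hvb)

        # oracle: common uniform sample over the joint bounding box
        lo = np.minimum(hva.points.min(0), hvb.points.min(0)) - 1.0
        hi = np.maximum(hva.points.max(0), hvb.points.max(0)) + 1.0
        u = np.random.default_rng(99).uniform(lo, hi, size=(120_000, 3))
        in_a = hva.kde(u.T) >= hva.threshold
        in_b = hvb.kde(u.T) >= hvb.threshold
        oracle = 2.0 * np.sum(in_a & in_b) / (in_a.sum() + in_b.sum())
        assert measured == pytest.approx(oracle, abs=0.05)


class TestDissimilarity:
    def test_self_dissimilarity_small(self):
        pts = np.random.default_rng(0).normal(size=(1000, 8))
        est = dissimilarity(pts, pts, n_boot=4, rng=np.random.default_rng(1),
                            cloud_size=600)
        assert est.mean < 0.15
        assert est.n_pairs == 16

    def test_disjoint_periods_near_one(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(500, 8))
        focal = rng.normal(size=(500, 8)) + 50.0
        est = dissimilarity(focal, ref, n_boot=3, rng=rng, cloud_size=500)
        assert est.mean > 0.95

    def test_monotone_under_increasing_shift(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(600, 8))
        means = []
        for delta in [0.0, 1.0, 2.0, 4.0, 8.0]:
            focal = rng.normal(size=(600, 8))
            focal[:, 0] += delta
            est = dissimilarity(focal, ref, n_boot=3,
                                rng=np.random.default_rng(7), cloud_size=500)
            means.append(est.mean)
        assert all(b >= a - 0.03 for a, b in zip(means, means[1:]))

    def test_symmetric_in_distribution(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(600, 8))
        b = rng.normal(size=(600, 8))
        b[:, 0] += 1.0
        e1 = dissimilarity(a, b, n_boot=4, rng=np.random.default_rng(21),
                           cloud_size=500)
        e2 = dissimilarity(b, a, n_boot=4, rng=np.random.default_rng(22),
                           cloud_size=500)
        mc_sd = max(e1.sd, e2.sd) / 2.0  # sd of the mean over 16 pairs
        assert abs(e1.mean - e2.mean) < 2 * max(2 * mc_sd, 0.02)


class TestMahalanobisNovelty:
    def test_zero_for_points_in_reference(self, rng):
        ref = rng.normal(size=(100, 4))
        d = mahalanobis_novelty(ref[:10], ref)
        assert np.allclose(d, 0.0)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        ref = rng.normal(size=(4000, 3))  # empirical cov ~ I
        focal = rng.normal(size=(20, 3)) + 2.0
        d = mahalanobis_novelty(focal, ref)
        d_euc = cdist(focal, ref).min(axis=1)
        assert np.allclose(d, d_euc, rtol=0.1, atol=0.05)

    def test_matches_double_loop_oracle(self, rng):
        ref = rng.normal(size=(60, 3)) @ np.diag([1.0, 2.0, 0.5])
        focal = rng.normal(size=(15, 3))
        vi = np.linalg.inv(np.cov(ref, rowvar=False))
        d = mahalanobis_novelty(focal, ref)
        for i in range(len(focal)):
            best = min(
                float(np.sqrt((focal[i] - r) @ vi @ (focal[i] - r))) for r in ref)
            assert d[i] == pytest.approx(best, rel=1e-10)
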