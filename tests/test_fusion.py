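import numpy as np
import pytest

import hydrospec as hs
from hydrospec.fusion import (
    SvrConfig,
    fuse_features,
    fusion_evaluate,
    fusion_fit,
    normalize_apply,
    normalize_fit,
    pca_apply,
    pca_fit,
    select_components,
    svr_fit,
)

# Published band lists for the three channels (THz)
POWER_BANDS = [0.53, 0.60, 0.76, 0.81, 1.08, 1.14, 1.26, 1.35, 1.45]
ABSORBANCE_BANDS = [0.54, 0.59, 1.19, 1.28, 1.34, 1.45]
TRANSMITTANCE_BANDS = [0.51, 0.54, 0.59, 1.24, 1.28, 1.30, 1.46]

# Printed per-component PCA contribution rates of the fused 22-band block
TABLE_CONTRIBUTIONS = [0.3332, 0.2452, 0.1631, 0.1085, 0.0574, 0.0256, 0.0189]


class TestFuseFeatures:
    def test_published_band_lists_fuse_to_22_columns(self, default_dataset):
        spectra, _ = default_dataset
        fused = fuse_features(
            {
                hs.Dimension.POWER: POWER_BANDS,
                hs.Dimension.ABSORBANCE: ABSORBANCE_BANDS,
                hs.Dimension.TRANSMITTANCE: TRANSMITTANCE_BANDS,
            },
            spectra,
        )
        assert fused.values.shape == (80, 22)
        # 0.54 THz selected in two channels gives two distinct columns
        dims_at_054 = [d for d, f in fused.columns if abs(f - 0.5418) < 2e-3]
        assert sorted(dims_at_054) == ["absorbance", "transmittance"]

    def test_empty_band_list_tolerated_with_warning(self, default_dataset):
        spectra, _ = default_dataset
        with pytest.warns(UserWarning, match="empty band list"):
            fused = fuse_features(
                {hs.Dimension.POWER: [], hs.Dimension.ABSORBANCE: ABSORBANCE_BANDS},
                spectra,
            )
        assert fused.values.shape[1] == len(ABSORBANCE_BANDS)

    def test_off_grid_frequency_named_in_error(self, default_dataset):
        spectra, _ = default_dataset
        with pytest.raises(ValueError, match="3.0000"):
            fuse_features({hs.Dimension.POWER: [3.0]}, spectra)


class TestNormalizer:
    def test_calibration_columns_standardized(self, rng):
        x = rng.normal(5, 3, size=(40, 6))
        norm = normalize_fit(x)
        z = normalize_apply(norm, x)
        assert np.max(np.abs(z.mean(axis=0))) < 1e-10
        assert np.max(np.abs(z.std(axis=0) - 1)) < 1e-10

    def test_constant_column_maps_to_zeros(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 7.0
        z = normalize_apply(normalize_fit(x), x)
        assert np.allclose(z[:, 1], 0.0)

    def test_no_leakage_into_prediction_rows(self, rng):
        x_cal = rng.normal(0, 1, size=(30, 4))
        x_pred = rng.normal(2, 1, size=(10, 4))
        z = normalize_apply(normalize_fit(x_cal), x_pred)
        assert np.min(np.abs(z.mean(axis=0))) > 0.5  # shifted, not recentred


class TestPca:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=5)
        x = np.outer(rng.normal(size=30), direction)
        red = pca_fit(x)
        assert red.k == 1
        assert red.contributions[0] == pytest.approx(1.0, abs=1e-12)

    def test_contributions_descending_and_sum_to_one(self, rng):
        red = pca_fit(rng.normal(size=(60, 22)))
        assert np.all(np.diff(red.contributions) <= 1e-12)
        assert red.contributions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigen_oracle(self, rng):
        x = rng.normal(size=(60, 22))
        red = pca_fit(x)
        xc = x - x.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        assert np.max(np.abs(red.contributions - eigvals[: len(red.contributions)] / eigvals.sum())) < 1e-10

    def test_score_covariance_diagonal_with_eigenvalue_entries(self, rng):
        x = rng.normal(size=(50, 8))
        red = pca_fit(x, threshold=1.0)
        scores = pca_apply(red, x)
        cov = scores.T @ scores / 1.0
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8

    def test_invalid_threshold(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(10, 3)), threshold=1.5)


class TestSelectComponents:
    def test_published_contributions_reach_95_at_seven(self):
        k, cum = select_components(TABLE_CONTRIBUTIONS + [0.0092, 0.0008], 0.95)
        assert k == 7
        assert cum == pytest.approx(0.9519, abs=1e-9)

    def test_single_component(self):
        assert select_components([1.0], 0.95) == (1, 1.0)

    def test_uniform_contributions(self):
        k, cum = select_components([1 / 22] * 22, 0.95)
        assert k == 21
        assert cum == pytest.approx(21 / 22, abs=1e-12)

    def test_insufficient_total_rejected(self):
        with pytest.raises(ValueError, match="below threshold"):
            select_components([0.4, 0.3], 0.95)


class TestSvr:
    def test_single_triple_grid_skips_search(self, rng):
        z = rng.normal(size=(30, 3))
        y = z @ np.array([1.0, -2.0, 0.5]) + 10
        model, table = svr_fit(z, y, SvrConfig(grid=[(0.5, 10.0, 0.01)]))
        assert model.params == (0.5, 10.0, 0.01)
        assert len(table) == 1

    def test_linear_target_well_approximated(self, rng):
        # linear responses sit in the RBF hypothesis closure: a flat-kernel
        # high-penalty cell fits them to ~1 % of the response spread, and
        # the cross-validated grid winner tracks the target almost exactly
        z = rng.normal(size=(40, 3))
        y = z @ np.array([0.5, 1.0, -0.7])
        tight, _ = svr_fit(z, y, SvrConfig(grid=[(2**-6, 64.0, 0.001)]))
        assert hs.rmse(tight.predict(z), y) < 0.05 * y.std()
        winner, _ = svr_fit(z, y, SvrConfig(seed=0))
        assert hs.pearson_r(winner.predict(z), y) > 0.999

    def test_prediction_invariant_to_training_order(self, rng):
        z = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        cfg = SvrConfig(grid=[(1.0, 4.0, 0.01)])
        m1, _ = svr_fit(z, y, cfg)
        perm = rng.permutation(30)
        m2, _ = svr_fit(z[perm], y[perm], cfg)
        probe = rng.normal(size=(5, 2))
        # agreement to the dual-solver tolerance, not bitwise: libsvm's
        # optimizer stops within a small duality gap that depends on order
        assert np.allclose(m1.predict(probe), m2.predict(probe), atol=1e-3)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            svr_fit(rng.normal(size=(10, 2)), np.ones(10), SvrConfig())


class TestFusionPipeline:
    def _fused_problem(self, seed=2):
        spectra, labels = hs.simulate_dataset(hs.SimConfig(seed=seed))
        y = labels["moisture_pct"].to_numpy()
        fused = fuse_features(
            {
                hs.Dimension.POWER: POWER_BANDS,
                hs.Dimension.ABSORBANCE: ABSORBANCE_BANDS,
                hs.Dimension.TRANSMITTANCE: TRANSMITTANCE_BANDS,
            },
            spectra,
        )
        split = hs.spxy_split(fused.values, y, 60)
        return fused, split, y

    def test_noiseless_data_fit_near_perfectly(self, quiet_config):
        import dataclasses

        cfg = dataclasses.replace(quiet_config, moisture_sd=10.0, seed=5)
        spectra, labels = hs.simulate_dataset(cfg)
        y = labels["moisture_pct"].to_numpy()
        fused = fuse_features({hs.Dimension.ABSORBANCE: ABSORBANCE_BANDS}, spectra)
        split = hs.spxy_split(fused.values, y, 60)
        pipe = fusion_fit(fused, y, split.calibration_indices)
        cal, pred, _ = fusion_evaluate(pipe, fused, split, y)
        assert cal.r > 0.999 and pred.r > 0.999

    def test_transforms_use_calibration_statistics_only(self):
        fused, split, y = self._fused_problem()
        cal = split.calibration_indices
        pipe = fusion_fit(fused, y, cal)
        # the normalizer's center/scale equal the calibration rows' moments
        assert np.allclose(pipe.normalizer.center, fused.values[cal].mean(axis=0))
        assert np.allclose(pipe.normalizer.scale, fused.values[cal].std(axis=0))
        # prediction-set scores are produced by the same frozen transform
        z_all = pipe.transform(fused.values)
        z_pred = pipe.transform(fused.values[split.prediction_indices])
        assert np.allclose(z_all[split.prediction_indices], z_pred)

    def test_scatter_table_covers_both_sets(self):
        fused, split, y = self._fused_problem()
        pipe = fusion_fit(fused, y, split.calibration_indices)
        _, _, scatter = fusion_evaluate(pipe, fused, split, y)
        assert len(scatter) == 80
        assert set(scatter["set"]) == {"calibration", "prediction"}
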