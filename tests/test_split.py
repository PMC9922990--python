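import numpy as np
import pytest

import hydrospec as hs
from hydrospec.split import compare_split_methods, n_cal_from_ratio


def naive_maxmin(d, n_cal):
    """Independent O(n^3) re-implementation of the max-min recursion with
    lowest-index tie-breaking, used as the oracle."""
    n = d.shape[0]
    best, pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, pair = d[i, j], (i, j)
    selected = list(pair)
    while len(selected) < n_cal:
        cand, cand_dist = None, -1.0
        for i in range(n):
            if i in selected:
                continue
            m = min(d[i, j] for j in selected)
            if m > cand_dist:
                cand, cand_dist = i, m
        selected.append(cand)
    return selected


def naive_spxy_distance(x, y):
    n = x.shape[0]
    dx = np.zeros((n, n))
    dy = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dx[i, j] = np.sqrt(np.sum((x[i] - x[j]) ** 2))
            dy[i, j] = abs(y[i] - y[j])
    d = np.zeros((n, n))
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    return d


class TestKennardStone:
    def test_two_point_selection_maximizes_distance(self):
        x = np.array([0.0, 1.0, 2.0, 10.0]).reshape(-1, 1)
        res = hs.ks_split(x, 2)
        assert sorted(res.calibration_indices) == [0, 3]

    def test_third_point_by_maxmin(self):
        x = np.array([0.0, 1.0, 2.0, 10.0]).reshape(-1, 1)
        res = hs.ks_split(x, 3)
        assert sorted(res.calibration_indices) == [0, 2, 3]

    def test_degenerate_identical_rows(self):
        x = np.ones((6, 3))
        res = hs.ks_split(x, 4)
        assert list(res.calibration_indices) == [0, 1, 2, 3]
        assert list(res.prediction_indices) == [4, 5]

    def test_out_of_range_n_cal(self):
        with pytest.raises(ValueError):
            hs.ks_split(np.ones((4, 2)), 4)

    def test_first_pair_achieves_global_max_distance(self, rng):
        x = rng.normal(size=(30, 4))
        res = hs.ks_split(x, 10)
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        i, j = res.calibration_indices[:2]
        assert d[i, j] == pytest.approx(d.max())


class TestSpxy:
    def test_identical_x_reduces_to_ks_on_y(self):
        x = np.ones((4, 2))
        y = np.array([0.0, 1.0, 2.0, 10.0])
        res = hs.spxy_split(x, y, 2)
        assert sorted(res.calibration_indices) == [0, 3]

    def test_constant_y_reduces_to_ks(self, rng):
        x = rng.normal(size=(12, 3))
        y = np.zeros(12)
        assert np.array_equal(
            hs.spxy_split(x, y, 6).calibration_indices,
            hs.ks_split(x, 6).calibration_indices,
        )

    def test_fully_degenerate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            hs.spxy_split(np.ones((4, 2)), np.ones(4), 2)

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=(8, 3))
            y = rng.normal(size=8)
            res = hs.spxy_split(x, y, 4)
            oracle = naive_maxmin(naive_spxy_distance(x, y), 4)
            assert list(res.calibration_indices) == oracle

    def test_joint_distance_widens_calibration_response_range(self):
        # the d_y term pulls response extremes into the calibration set:
        # SPXY's calibration y-range dominates KS's on almost all random
        # problems (it need not contain the exact extremes when predictor
        # distances dominate the joint metric)
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(15, 4))
            y = rng.normal(size=15)
            yspxy = y[hs.spxy_split(x, y, 5).calibration_indices]
            yks = y[hs.ks_split(x, 5).calibration_indices]
            wins += (yspxy.max() - yspxy.min()) >= (yks.max() - yks.min())
        assert wins >= 90


class TestProperties:
    def test_partition_is_exact(self, rng):
        x = rng.normal(size=(20, 5))
        res = hs.ks_split(x, 15)
        both = np.concatenate([res.calibration_indices, res.prediction_indices])
        assert sorted(both) == list(range(20))

    def test_permutation_equivariance(self, rng):
        # row i of x[perm] is x[perm[i]]: mapping selections back through
        # perm must recover the original partition when all pairwise
        # distances are distinct
        x = rng.normal(size=(15, 3))
        a = set(int(i) for i in hs.ks_split(x, 6).calibration_indices)
        perm = rng.permutation(15)
        shuffled = hs.ks_split(x[perm], 6)
        assert {int(perm[i]) for i in shuffled.calibration_indices} == a

    def test_ratio_round_half_up(self):
        assert n_cal_from_ratio(80, 0.75) == 60
        assert n_cal_from_ratio(10, 0.75) == 8
        assert n_cal_from_ratio(6, 0.75) == 5


class TestCompareSplitMethods:
    def _small(self):
        cfg = hs.SimConfig(seed=4, leaves_per_level=8)
        spectra, labels = hs.simulate_dataset(cfg)
        return spectra, labels["moisture_pct"].to_numpy()

    def test_table_shape_and_determinism(self):
        spectra, y = self._small()
        table = compare_split_methods(spectra, y)
        assert len(table) == 6
        assert set(table["method"]) == {"KS", "SPXY"}
        assert table["error"].eq("").all()
        assert table.equals(compare_split_methods(spectra, y))

    def test_noiseless_linear_data_fits_perfectly(self, quiet_config):
        import dataclasses

        cfg = dataclasses.replace(quiet_config, moisture_sd=10.0, leaves_per_level=8)
        spectra, labels = hs.simulate_dataset(cfg)
        table = compare_split_methods(
            {hs.Dimension.ABSORBANCE: spectra[hs.Dimension.ABSORBANCE]},
            labels["moisture_pct"].to_numpy(),
        )
        assert np.all(table["rc"] > 0.9999)
        assert np.all(table["rmsec"] < 0.1)
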