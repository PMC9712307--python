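from collections import deque

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symconn import (
    extract_clusters,
    fdr_correct,
    hedges_g,
    make_symmetric_grid,
    motion_control,
    network_group_test,
    spearman_screen,
    voxelwise_group_test,
)
from symconn.image import MetricMap


def maps_from_matrix(Y, grid_dims=(5, 4, 4)):
    """(subjects, voxels) matrix -> list of MetricMaps on a small grid."""
    grid = make_symmetric_grid(grid_dims)
    n_vox = int(np.prod(grid_dims))
    assert Y.shape[1] <= n_vox
    mask = np.zeros(grid_dims, dtype=bool)
    mask.ravel()[: Y.shape[1]] = True
    out = []
    for row in Y:
        vals = np.full(grid_dims, np.nan)
        vals[mask] = row
        out.append(MetricMap(values=vals, mask=mask, grid=grid, metric="EC"))
    return out, mask


class TestVoxelwiseGroupTest:
    def test_reduces_to_pooled_two_sample_t(self, rng):
        Y = rng.standard_normal((16, 30))
        groups = ["TYP"] * 8 + ["ADHD"] * 8
        maps, mask = maps_from_matrix(Y)
        res = voxelwise_group_test(maps, groups, min_cluster=1)
        t_oracle, p_oracle = stats.ttest_ind(Y[:8], Y[8:], axis=0, equal_var=True)
        np.testing.assert_allclose(res.t_map[mask], t_oracle, atol=1e-10)
        np.testing.assert_allclose(res.p_map[mask], p_oracle, atol=1e-10)
        assert res.df == 14

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        n = 24
        Y = rng.standard_normal((n, 5))
        groups = ["TYP", "ADHD"] * 12
        cov = pd.DataFrame({"age": rng.uniform(7, 18, n), "iq": rng.normal(100, 15, n)})
        maps, mask = maps_from_matrix(Y)
        res = voxelwise_group_test(maps, groups, covariates=cov, min_cluster=1)
        indicator = np.array([1.0 if g == "TYP" else 0.0 for g in groups])
        X = sm.add_constant(
            np.column_stack([indicator, cov["age"] - cov["age"].mean(), cov["iq"] - cov["iq"].mean()])
        )
        for j in range(5):
            fit = sm.OLS(Y[:, j], X).fit()
            assert res.t_map[mask][j] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert res.p_map[mask][j] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_null_type_one_error_rate(self, rng):
        Y = rng.standard_normal((20, 500))
        groups = list(rng.permutation(["TYP"] * 10 + ["ADHD"] * 10))
        maps, mask = maps_from_matrix(Y, grid_dims=(10, 10, 5))
        res = voxelwise_group_test(maps, groups, min_cluster=1)
        frac = float((res.p_map[mask] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_constant_covariate_rejected(self, rng):
        Y = rng.standard_normal((12, 4))
        maps, _ = maps_from_matrix(Y)
        cov = pd.DataFrame({"c": np.ones(12)})
        with pytest.raises(ValueError, match="collinear"):
            voxelwise_group_test(maps, ["TYP", "ADHD"] * 6, covariates=cov)

    def test_q_map_never_below_p_map(self, rng):
        Y = rng.standard_normal((14, 50))
        maps, mask = maps_from_matrix(Y)
        res = voxelwise_group_test(maps, ["TYP", "ADHD"] * 7, min_cluster=1)
        assert (res.q_map[mask] >= res.p_map[mask] - 1e-12).all()


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestFDR:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(fdr_correct(np.ones(5)), 1.0)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.037]), [0.037])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_correct(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


def flood_fill_oracle(binary, nn_level):
    """Brute-force BFS connected components; returns frozensets of voxel tuples."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                order = sum(x != 0 for x in (di, dj, dk))
                if 1 <= order <= nn_level:
                    offsets.append((di, dj, dk))
    seen = np.zeros(binary.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            cur = queue.popleft()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= c < s for c, s in zip(nb, binary.shape)) and binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestExtractClusters:
    def test_empty_map(self):
        assert extract_clusters(np.zeros((4, 4, 4), dtype=bool)) == []

    def test_corner_touching_voxels(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        assert len(extract_clusters(vol, nn_level=3, min_size=1)) == 1
        assert len(extract_clusters(vol, nn_level=1, min_size=1)) == 2

    def test_edge_touching_voxels(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[0, 0, 0] = vol[0, 1, 1] = True
        assert len(extract_clusters(vol, nn_level=2, min_size=1)) == 1
        assert len(extract_clusters(vol, nn_level=1, min_size=1)) == 2

    @pytest.mark.parametrize("nn_level", [1, 2, 3])
    def test_matches_flood_fill_oracle(self, rng, nn_level):
        for _ in range(10):
            vol = rng.random((8, 8, 8)) < 0.3
            clusters = extract_clusters(vol, nn_level=nn_level, min_size=1)
            oracle = flood_fill_oracle(vol, nn_level)
            assert {c.size_voxels for c in clusters} == {len(c) for c in oracle}
            assert sum(c.size_voxels for c in clusters) == int(vol.sum())

    def test_min_size_filtering(self, rng):
        vol = np.zeros((6, 6, 6), dtype=bool)
        vol[:2, :2, :2] = True  # size 8
        vol[5, 5, 5] = True  # size 1
        out = extract_clusters(vol, nn_level=1, min_size=2)
        assert len(out) == 1 and out[0].size_voxels == 8

    def test_labels_ordered_by_size_then_peak(self):
        vol = np.zeros((6, 6, 6), dtype=bool)
        vol[0, 0, :3] = True
        vol[3, 3, :5] = True
        out = extract_clusters(vol, nn_level=1, min_size=1)
        assert [c.label for c in out] == [1, 2]
        assert out[0].size_voxels == 5 and out[1].size_voxels == 3

    def test_peak_is_max_abs_t(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[0, 0, :4] = True
        t_map = np.zeros((4, 4, 4))
        t_map[0, 0, :4] = [1.0, -5.0, 2.0, 3.0]
        out = extract_clusters(vol, nn_level=1, min_size=1, stat_map=t_map)
        assert out[0].peak_index == (0, 0, 1)
        assert out[0].peak_t == -5.0

    def test_axis_permutation_invariance(self, rng):
        vol = rng.random((6, 6, 6)) < 0.25
        base = extract_clusters(vol, nn_level=3, min_size=1)
        permuted = extract_clusters(np.transpose(vol, (2, 0, 1)), nn_level=3, min_size=1)
        assert sorted(c.size_voxels for c in base) == sorted(c.size_voxels for c in permuted)

    def test_unknown_nn_level_rejected(self):
        with pytest.raises(ValueError, match="nn_level"):
            extract_clusters(np.zeros((3, 3, 3), dtype=bool), nn_level=4)


class TestHedgesG:
    def test_small_sample_correction_at_n6(self):
        # J = 1 - 3/(4*6 - 9) = 0.8 exactly
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        sp = np.sqrt(((2 * 1.0) + (2 * 4.0)) / 4.0)  # pooled SD, hand-computed
        expected = 0.8 * (2.0 - 4.0) / sp
        assert hedges_g(x, y) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.0119288512538814)

    def test_zero_for_identical_groups(self, rng):
        x = rng.standard_normal(10)
        assert hedges_g(x, x) == 0.0

    def test_converges_to_cohens_d(self, rng):
        x = rng.standard_normal(5000) + 0.5
        y = rng.standard_normal(5000)
        d = (x.mean() - y.mean()) / np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        assert hedges_g(x, y) == pytest.approx(d, rel=1e-3)

    def test_mean_estimate_recovers_planted_effect(self, rng):
        gs = []
        for _ in range(200):
            x = rng.standard_normal(50) + 0.6
            y = rng.standard_normal(50)
            gs.append(hedges_g(x, y))
        assert 0.5 <= np.mean(gs) <= 0.7

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            hedges_g(np.ones(3), np.ones(3))


class TestNetworkGroupTest:
    def test_sign_convention_and_significance(self, rng):
        n = 30
        summary = pd.DataFrame(
            {
                "netA_EC": np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)],  # higher in ADHD
                "netB_EC": rng.standard_normal(2 * n),
            }
        )
        groups = ["TYP"] * n + ["ADHD"] * n
        out = network_group_test(summary, groups)
        assert out.loc["netA_EC", "t_statistic"] < 0  # ADHD higher -> negative
        assert out.loc["netA_EC", "hedges_g"] < 0
        assert out.loc["netA_EC", "significant"]
        assert np.sign(out.loc["netA_EC", "t_statistic"]) == np.sign(out.loc["netA_EC", "hedges_g"])

    def test_null_shift_gives_zero(self):
        summary = pd.DataFrame({"m": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = network_group_test(summary, ["TYP"] * 3 + ["ADHD"] * 3)
        assert out.loc["m", "t_statistic"] == pytest.approx(0.0)
        assert out.loc["m", "hedges_g"] == pytest.approx(0.0)

    def test_welch_switch_changes_df_path(self, rng):
        summary = pd.DataFrame({"m": np.r_[rng.normal(0, 1, 10), rng.normal(0, 5, 40)]})
        groups = ["TYP"] * 10 + ["ADHD"] * 40
        student = network_group_test(summary, groups, welch=False)
        welch = network_group_test(summary, groups, welch=True)
        assert student.loc["m", "p_value"] != welch.loc["m", "p_value"]


class TestSpearmanScreen:
    @staticmethod
    def frame(n, rng):
        return (
            pd.DataFrame({"net": rng.standard_normal(n)}),
            pd.DataFrame({"age": rng.uniform(7, 18, n)}),
        )

    def test_perfect_monotone_is_one(self):
        summary = pd.DataFrame({"net": [1.0, 4.0, 9.0, 16.0, 25.0, 36.0]})
        cov = pd.DataFrame({"age": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        out = spearman_screen(summary, cov)
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)
        assert out.loc[0, "band"] == "significant"

    def test_null_quantile_matches_fisher_band(self, rng):
        rhos = []
        for _ in range(500):
            s, c = self.frame(80, rng)
            out = spearman_screen(s, c)
            rhos.append(abs(out.loc[0, "spearman_rho"]))
        # 95th percentile of |rho| under the null at n=80 is ~0.22
        assert np.quantile(rhos, 0.95) == pytest.approx(0.22, abs=0.03)

    def test_cohort_panels_present(self, rng):
        n = 20
        summary = pd.DataFrame({"net": rng.standard_normal(n)})
        cov = pd.DataFrame({"age": rng.uniform(7, 18, n)})
        groups = ["TYP"] * 10 + ["ADHD"] * 10
        out = spearman_screen(summary, cov, groups=groups)
        assert set(out["cohort"]) == {"overall", "TYP", "ADHD"}

    def test_constant_covariate_reported_missing(self, rng):
        summary = pd.DataFrame({"net": rng.standard_normal(8)})
        cov = pd.DataFrame({"hand": np.ones(8)})
        out = spearman_screen(summary, cov)
        assert out.loc[0, "band"] == "missing"
        assert np.isnan(out.loc[0, "spearman_rho"])

    def test_band_rule(self, rng):
        # banding is a pure function of p: check via planted strong correlation
        n = 40
        x = np.arange(n, dtype=float)
        summary = pd.DataFrame({"net": x + rng.normal(0, 1, n)})
        cov = pd.DataFrame({"age": x})
        out = spearman_screen(summary, cov)
        assert out.loc[0, "p_value"] < 0.01 and out.loc[0, "band"] == "significant"

    def test_small_cohort_rejected(self, rng):
        s, c = self.frame(4, rng)
        with pytest.raises(ValueError, match="fewer than 5"):
            spearman_screen(s, c)


class TestMotionControl:
    def test_planted_fd_shift_detected(self, rng):
        hits = 0
        for _ in range(100):
            fd = np.r_[rng.normal(0.2, 0.05, 40), rng.normal(0.25, 0.05, 40)]
            res = motion_control(fd, ["TYP"] * 40 + ["ADHD"] * 40)
            hits += res["p_value"] < 0.01
        assert hits >= 95  # 1 pooled-SD shift at n=40+40 is near-surely detected

    def test_null_p_uniformity(self, rng):
        ps = []
        for _ in range(200):
            fd = rng.normal(0.2, 0.05, 30)
            ps.append(motion_control(fd, ["TYP"] * 15 + ["ADHD"] * 15)["p_value"])
        assert 0.2 < np.mean(ps) < 0.8
        assert (np.array(ps) < 0.05).mean() < 0.12

    def test_constant_fd_rejected(self):
        with pytest.raises(ValueError):
            motion_control(np.full(10, 0.2), ["TYP"] * 5 + ["ADHD"] * 5)
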