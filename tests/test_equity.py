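import numpy as np
import pandas as pd
import pytest

import nearsource as ns
from nearsource.spatial import SpatialWeights


def _bg(i, dist, poc=0.5, li=0.5, x=None, y=0.0):
    return ns.BlockGroup(
        bg_id=f"BG{i:03d}", centroid_x=dist * 1000.0 if x is None else x,
        centroid_y=y, distance_km=dist, pop_by_age=(100,) * 9,
        poc_frac=poc, li_frac=li,
        baseline_mortality_by_age=(100.0,) * 9, asthma_incidence_0_14=1000.0)


class TestDistanceQuintiles:
    def test_even_split(self):
        bgs = [_bg(i, float(i + 1)) for i in range(10)]
        q = ns.assign_distance_quintiles(bgs)
        assert list(q.sort_index()) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_remainder_goes_to_nearest_quintiles(self):
        bgs = [_bg(i, float(i + 1)) for i in range(12)]
        q = ns.assign_distance_quintiles(bgs)
        sizes = q.value_counts().sort_index().tolist()
        assert sizes == [3, 3, 2, 2, 2]

    def test_ties_still_partition_evenly(self):
        bgs = [_bg(i, 7.0) for i in range(10)]
        q = ns.assign_distance_quintiles(bgs)
        assert sorted(q.value_counts()) == [2, 2, 2, 2, 2]

    def test_too_few_blockgroups_rejected(self):
        with pytest.raises(ValueError):
            ns.assign_distance_quintiles([_bg(i, 1.0) for i in range(4)])

    def test_quintile_mean_distance_ordered(self, clustered_run,
                                            small_region):
        tbl = clustered_run["quintile_table"]
        assert tbl["distance_km"].is_monotonic_increasing


class TestQuintileTable:
    def test_uniform_demographics_flat_table(self):
        bgs = [_bg(i, float(i + 1), poc=0.3, li=0.2) for i in range(10)]
        exp = pd.Series(1.0, index=[bg.bg_id for bg in bgs])
        tbl = ns.quintile_table(bgs, exp)
        assert np.allclose(tbl["poc_pct"], 30.0)
        assert np.allclose(tbl["li_pct"], 20.0)

    def test_monotone_exposure_gives_monotone_quintile_means(self):
        bgs = [_bg(i, float(i + 1)) for i in range(15)]
        exp = pd.Series({bg.bg_id: 100.0 / bg.distance_km for bg in bgs})
        tbl = ns.quintile_table(bgs, exp)
        assert tbl["exposure_ppb"].is_monotonic_decreasing

    def test_planted_gradient_orders_poc(self, clustered_run):
        tbl = clustered_run["quintile_table"]
        assert tbl.loc[0, "poc_pct"] > tbl.loc[4, "poc_pct"]

    def test_quintiles_partition_region(self, clustered_run):
        tbl = clustered_run["quintile_table"]
        assert tbl["n_blockgroups"].sum() == 500
        assert tbl["n_blockgroups"].max() - tbl["n_blockgroups"].min() <= 1


class TestStratifyByPoc:
    def test_single_bin_when_demographics_constant(self):
        bgs = [_bg(i, float(i + 1), poc=0.5) for i in range(8)]
        vals = pd.Series(1.0, index=[bg.bg_id for bg in bgs])
        tbl = ns.stratify_by_poc(bgs, vals)
        assert tbl["n"].tolist() == [0, 0, 8, 0, 0]

    def test_quartiles_match_order_statistics(self):
        vals = [3.0, 9.0, 1.0, 7.0, 5.0, 11.0]
        bgs = [_bg(i, float(i + 1), poc=0.45) for i in range(6)]
        series = pd.Series(vals, index=[bg.bg_id for bg in bgs])
        tbl = ns.stratify_by_poc(bgs, series)
        row = tbl.iloc[2]
        q1, med, q3 = np.percentile(np.array(vals), [25, 50, 75])
        assert row["q1"] == q1 and row["median"] == med and row["q3"] == q3
        assert row["mean"] == pytest.approx(np.mean(vals))

    def test_bins_partition(self, clustered_run, small_region):
        tbl = ns.stratify_by_poc(
            small_region.block_groups,
            pd.Series(1.0, index=[bg.bg_id for bg in small_region.block_groups]))
        assert tbl["n"].sum() == len(small_region.block_groups)


class TestIntersectionalGroups:
    def test_group_counts_sum_to_n(self, clustered_run):
        tbl = clustered_run["intersectional"]
        assert tbl["n"].sum() == 500

    def test_no_planted_structure_groups_similar(self):
        sc = ns.generate_region(500, seed=21)
        met_free = pd.Series(
            np.random.default_rng(3).uniform(4, 6, 500),
            index=[bg.bg_id for bg in sc.block_groups])
        tbl = ns.intersectional_groups(sc.block_groups, met_free)
        means = tbl["mean_ppb"]
        assert means.max() - means.min() < 0.5

    def test_degenerate_demographics_single_group(self):
        bgs = [_bg(i, float(i + 1), poc=0.5, li=0.5) for i in range(6)]
        exp = pd.Series(1.0, index=[bg.bg_id for bg in bgs])
        tbl = ns.intersectional_groups(bgs, exp).set_index("group")
        assert tbl.loc["HH", "n"] == 6
        assert tbl.loc[["HL", "LH", "LL"], "n"].sum() == 0
        assert np.isnan(tbl.loc["LL", "mean_ppb"])


class TestWeights:
    def test_no_self_loops_and_row_sums(self, small_region):
        w = ns.build_weights(small_region.block_groups, k=8)
        for i, (nbrs, ws) in enumerate(zip(w.neighbors, w.weights)):
            assert i not in nbrs
            assert sum(ws) == pytest.approx(1.0)

    def test_collinear_union_symmetrization(self):
        bgs = [_bg(0, 1.0, x=0.0), _bg(1, 2.0, x=1000.0), _bg(2, 3.0, x=3000.0)]
        w = ns.build_weights(bgs, k=1)
        assert sorted(w.neighbors[1]) == [0, 2]  # middle gains reverse edge

    def test_k_too_large_rejected(self, small_region):
        with pytest.raises(ValueError):
            ns.build_weights(small_region.block_groups[:5], k=5)


class TestMoransI:
    def brute_force(self, x, w):
        W = w.dense()
        n = len(x)
        z = x - x.mean()
        num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        return n / W.sum() * num / (z @ z)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(8)
        for n in (7, 12, 20):
            pts = rng.uniform(0, 10, (n, 2))
            bgs = [_bg(i, 1.0 + i, x=pts[i, 0] * 1000, y=pts[i, 1] * 1000)
                   for i in range(n)]
            w = ns.build_weights(bgs, k=3)
            x = rng.normal(size=n)
            i_obs, _ = ns.morans_i(x, w, permutations=0)
            assert i_obs == pytest.approx(self.brute_force(x, w), abs=1e-12)

    def test_checkerboard_is_minus_one(self):
        # 2x2 rook lattice, alternating values
        adj = {0: [1, 2], 1: [0, 3], 2: [0, 3], 3: [1, 2]}
        w = SpatialWeights.from_adjacency(adj)
        i_obs, _ = ns.morans_i(np.array([1.0, -1.0, -1.0, 1.0]), w,
                               permutations=0)
        assert i_obs == pytest.approx(-1.0, abs=1e-12)

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(10)
        n = 15
        bgs = [_bg(i, 1.0 + i, x=rng.uniform(0, 1e4), y=rng.uniform(0, 1e4))
               for i in range(n)]
        w = ns.build_weights(bgs, k=3)
        x = rng.normal(size=n)
        sims = [ns.morans_i(rng.permutation(x), w, permutations=0)[0]
                for _ in range(2000)]
        assert np.mean(sims) == pytest.approx(-1.0 / (n - 1), abs=0.02)

    def test_smooth_gradient_positive(self):
        bgs = [_bg(i, 1.0 + i, x=i * 1000.0) for i in range(12)]
        w = ns.build_weights(bgs, k=2)
        i_obs, p = ns.morans_i(np.arange(12, dtype=float), w, seed=4)
        assert i_obs > 0
        assert p < 0.05

    def test_constant_values_rejected(self, small_region):
        w = ns.build_weights(small_region.block_groups, k=4)
        with pytest.raises(ValueError):
            ns.morans_i(np.ones(len(small_region.block_groups)), w)


@pytest.fixture(scope="module")
def sim_design():
    sc = ns.generate_region(400, seed=42)
    w = ns.build_weights(sc.block_groups, k=8)
    rng = np.random.default_rng(7)
    x = rng.normal(size=400)
    X = pd.DataFrame({"x": x})
    eps = rng.normal(0, 0.5, 400)
    return w, X, x, eps


class TestRegressions:
    def test_ols_exact_fit_recovery(self):
        rng = np.random.default_rng(2)
        poc = rng.uniform(0, 1, 50)
        X = pd.DataFrame({"poc": poc, "li": rng.uniform(0, 1, 50)})
        y = 2.0 + 3.0 * poc
        res = ns.ols_fit(y, X)
        assert res.params["intercept"] == pytest.approx(2.0, abs=1e-10)
        assert res.params["poc"] == pytest.approx(3.0, abs=1e-10)
        assert res.params["li"] == pytest.approx(0.0, abs=1e-10)

    def test_ols_invariant_to_ordering(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=40)})
        y = 1.0 + 0.5 * X["a"].to_numpy() + rng.normal(0, 0.1, 40)
        r1 = ns.ols_fit(y, X)
        perm = rng.permutation(40)
        r2 = ns.ols_fit(y[perm], X.iloc[perm].reset_index(drop=True))
        assert np.allclose(r1.params, r2.params)

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                          "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError):
            ns.ols_fit(np.arange(4.0), X)

    def test_slm_parameter_recovery(self, sim_design):
        w, X, x, eps = sim_design
        W = w.dense()
        y = np.linalg.solve(np.eye(400) - 0.5 * W, 1.0 + 2.0 * x + eps)
        res = ns.slm_fit(y, X, w, seed=1)
        assert res.converged
        assert res.spatial_param == pytest.approx(0.5, abs=0.1)
        assert res.params["intercept"] == pytest.approx(1.0, abs=0.15)
        assert res.params["x"] == pytest.approx(2.0, abs=0.15)

    def test_slm_nested_at_rho_zero(self, sim_design):
        w, X, x, eps = sim_design
        y = 1.0 + 2.0 * x + eps
        r_ols = ns.ols_fit(y, X, w, seed=1)
        r_slm = ns.slm_fit(y, X, w, seed=1)
        assert abs(r_slm.log_likelihood - r_ols.log_likelihood) < 2.0

    def test_sem_degenerate_matches_ols(self, sim_design):
        w, X, x, eps = sim_design
        y = 1.0 + 2.0 * x + eps
        r_ols = ns.ols_fit(y, X, w, seed=1)
        r_sem = ns.sem_fit(y, X, w, seed=1)
        assert abs(r_sem.spatial_param) < 0.2
        assert np.allclose(r_sem.params, r_ols.params, atol=0.05)

    def test_sem_parameter_recovery(self, sim_design):
        w, X, x, eps = sim_design
        W = w.dense()
        u = np.linalg.solve(np.eye(400) - 0.6 * W, eps)
        y = 1.0 + 2.0 * x + u
        res = ns.sem_fit(y, X, w, seed=1)
        assert res.spatial_param == pytest.approx(0.6, abs=0.15)
        assert res.params["x"] == pytest.approx(2.0, abs=0.15)

    def test_spatial_param_within_stationarity_bounds(self, clustered_run):
        for name in ("SLM", "SEM"):
            res = clustered_run["regressions"][name]
            assert abs(res.spatial_param) < 1.0
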