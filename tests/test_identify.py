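import numpy as np
import pandas as pd
import pytest

from cnkit.evaluate import nmi
from cnkit.identify import (
    _assignment_cost,
    cc_representations,
    cfidf_weighted_graph,
    cne_bandwidths,
    cne_representations,
    identify_cc,
    identify_cfidf,
    identify_cne,
    overall_ct_frequencies,
    spatially_regularized_kmeans,
)
from cnkit.synthetic import SyntheticTissueSpec, simulate_tissue
from cnkit.tissue import build_delaunay_graphs
from tests.conftest import make_table


class TestOverallFrequencies:
    def test_half_and_half(self):
        t = make_table([(i, 0.1 * i**2) for i in range(10)], "aaaaabbbbb")
        f = overall_ct_frequencies(t).overall
        assert f["a"] == 0.5 and f["b"] == 0.5

    def test_single_ct(self):
        t = make_table([(0, 0), (1, 0), (2, 1)], "aaa")
        assert overall_ct_frequencies(t).overall.to_dict() == {"a": 1.0}

    def test_normalized_on_random_tables(self):
        cells, _ = simulate_tissue(SyntheticTissueSpec(n_cells=300, n_cns=3, seed=2))
        assert overall_ct_frequencies(cells).overall.sum() == pytest.approx(1.0)


class TestCCRepresentations:
    def test_window_histogram(self):
        # c0's 3 nearest points including itself are {c0:a, c1:a, c2:b}
        t = make_table([(0, 0), (1, 0), (2, 0), (10, 0)], "aabb")
        r = cc_representations(t, m=3).values
        assert r.loc["c0", "a"] == pytest.approx(2 / 3)
        assert r.loc["c0", "b"] == pytest.approx(1 / 3)

    def test_m1_is_one_hot(self):
        t = make_table([(0, 0), (1, 0), (2, 0)], "aba")
        r = cc_representations(t, m=1).values
        assert r.loc["c1"].to_dict() == {"a": 0.0, "b": 1.0}

    def test_m_exceeding_image_clamped_with_warning(self):
        t = make_table([(0, 0), (1, 0), (2, 0)], "aba")
        with pytest.warns(UserWarning, match="clamped"):
            r = cc_representations(t, m=10).values
        assert np.allclose(r.sum(axis=1), 1.0)


class TestBandwidths:
    def grid_oracle_sigma(self, dists, perp, lo=0.05, hi=50.0, n=20001):
        """Independent dense grid search of the perplexity curve."""
        sigmas = np.exp(np.linspace(np.log(lo), np.log(hi), n))
        best, best_err = None, np.inf
        for s in sigmas:
            q = np.exp(-np.asarray(dists) ** 2 / (2 * s**2))
            p = q / q.sum()
            h = -(p * np.log2(p)).sum()
            err = abs(2**h - perp)
            if err < best_err:
                best, best_err = s, err
        return best

    def test_two_neighbor_profile_matches_grid_search(self):
        # clamped distances {1, 1, 2} (self, nn, far), perp = 2.5
        t = make_table([(0, 0), (1, 0), (-2, 0)], "aaa")
        bw = cne_bandwidths(t, perp=2.5)
        assert bw.dist[0, :3].tolist() == [1.0, 1.0, 2.0]
        sig = bw.sigma[0]
        oracle = self.grid_oracle_sigma([1.0, 1.0, 2.0], 2.5)
        q = np.exp(-np.array([1.0, 1.0, 2.0]) ** 2 / (2 * sig**2))
        p = q / q.sum()
        achieved = 2 ** (-(p * np.log2(p)).sum())
        assert achieved == pytest.approx(2.5, abs=1e-5)
        assert sig == pytest.approx(oracle, rel=1e-3)

    def test_equidistant_support_is_flat_and_uniform(self):
        # center cell: 4 exactly equidistant neighbors; perplexity curve is
        # constant so the solver flags it and p stays uniform
        ring = [(1, 0), (0, 1), (-1, 0), (0, -1)]
        t = make_table([(0, 0)] + ring, "a" * 5)
        bw = cne_bandwidths(t, perp=3.0)
        assert bw.flags.loc["c0", "flat"]
        p = bw.conditional()[0]
        p = p[p > 0]
        assert np.allclose(p, 1 / 5)

    def test_infeasible_target_clamped_to_uniform(self):
        t = make_table([(0, 0), (1, 0), (3, 0), (7, 0)], "aaaa")
        with pytest.warns(UserWarning, match="clamped"):
            bw = cne_bandwidths(t, perp=50.0)
        p = bw.conditional()
        assert np.allclose(p[p > 0], 0.25, atol=1e-3)

    def test_conditional_rows_sum_to_one(self, planted_tissue):
        cells, _ = planted_tissue
        bw = cne_bandwidths(cells, perp=10.0)
        assert np.allclose(bw.conditional().sum(axis=1), 1.0)

    def test_achieved_perplexity_matches_target(self, planted_tissue):
        cells, _ = planted_tissue
        bw = cne_bandwidths(cells, perp=15.0)
        p = bw.conditional()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        ok = ~bw.flags["flat"] & ~bw.flags["clamped"] & ~bw.flags["no_neighbors"]
        assert np.abs(2 ** h[ok.to_numpy()] - 15.0).max() < 1e-4

    def test_single_cell_image_flagged(self):
        t1 = make_table([(0, 0)], "a", image="imgA")
        t2 = make_table([(0, 0), (1, 0), (0, 1)], "abb", image="imgB", start=1)
        from cnkit.tissue import CellTable

        t = CellTable(pd.concat([t1.df, t2.df]))
        bw = cne_bandwidths(t, perp=2.0)
        assert bw.flags.loc["c0", "no_neighbors"]
        assert np.isnan(bw.sigma[0])


class TestCNERepresentations:
    def test_pure_neighborhood_gets_idf_weight(self):
        # image A all CT a, image B all CT b; F(a) = 0.5 -> vector (ln 2, 0)
        ta = make_table([(0, 0), (1, 0), (0, 1), (1, 1)], "aaaa", image="imgA")
        tb = make_table(
            [(0, 0), (1, 0), (0, 1), (1, 1)], "bbbb", image="imgB", start=4
        )
        from cnkit.tissue import CellTable

        t = CellTable(pd.concat([ta.df, tb.df]))
        bw = cne_bandwidths(t, perp=2.0)
        reps = cne_representations(bw, overall_ct_frequencies(t)).values
        assert reps.loc["c0", "a"] == pytest.approx(np.log(2))
        assert reps.loc["c0", "b"] == 0.0

    def test_rows_sum_to_one_before_idf(self, planted_tissue):
        cells, _ = planted_tissue
        bw = cne_bandwidths(cells, perp=10.0)
        raw = cne_representations(bw, overall_ct_frequencies(cells), idf=False)
        assert raw.stage == "raw_density"
        assert np.allclose(raw.values.sum(axis=1), 1.0)

    def test_single_ct_vocabulary_degenerates_to_zero(self):
        t = make_table([(0, 0), (1, 0), (0, 1)], "aaa")
        bw = cne_bandwidths(t, perp=2.0)
        with pytest.warns(UserWarning, match="single-CT"):
            reps = cne_representations(bw, overall_ct_frequencies(t))
        assert (reps.values.to_numpy() == 0).all()


class TestSpatiallyRegularizedKmeans:
    def test_lambda_zero_matches_sklearn_lloyd(self):
        from sklearn.cluster import KMeans, kmeans_plusplus

        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.3, (40, 3)), rng.normal(3, 0.3, (40, 3)),
             rng.normal((0, 5, 0), 0.3, (40, 3))]
        )
        df = pd.DataFrame(X, index=pd.Index([f"c{i}" for i in range(120)], name="cell_id"))
        mine = spatially_regularized_kmeans(df, None, k=3, lam=0.0, seed=4)
        init, _ = kmeans_plusplus(X, n_clusters=3, random_state=4)
        ref = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300, tol=0.0,
                     algorithm="lloyd").fit(X)
        assert nmi(mine, pd.Series(ref.labels_, index=df.index)) == pytest.approx(1.0)

    def test_orthogonal_blocks_split_perfectly(self, two_block_table):
        reps = cc_representations(two_block_table, m=5)
        lab = spatially_regularized_kmeans(reps, None, k=2, lam=0.0, seed=0)
        truth = pd.Series([0] * 40 + [1] * 40, index=two_block_table.cell_ids)
        assert nmi(lab, truth) == pytest.approx(1.0)

    def test_assignment_cost_matches_hand_oracle(self):
        # direct evaluation of the regularized objective on a 2-centroid case
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]])
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        labels = np.array([0, 1, 0])
        # cell 2 neighbors cells 0 and 1
        indptr = np.array([0, 1, 2, 4])
        indices = np.array([2, 2, 0, 1])
        lam = 0.25
        cost = _assignment_cost(X, centers, labels, indptr, indices, lam)
        for x in range(3):
            nbrs = indices[indptr[x]:indptr[x + 1]]
            for n in range(2):
                expected = ((X[x] - centers[n]) ** 2).sum() + lam / len(nbrs) * sum(
                    ((centers[n] - centers[labels[y]]) ** 2).sum() for y in nbrs
                )
                assert cost[x, n] == pytest.approx(expected)

    def test_tied_cell_follows_neighbor_labels(self):
        # a cell equidistant to both centroids takes its neighbors' CN
        X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        labels = np.array([0, 1, 1, 0])
        indptr = np.array([0, 0, 0, 0, 2])  # only the tied cell has neighbors
        indices = np.array([1, 2])
        cost = _assignment_cost(X, centers, labels, indptr, indices, 0.25)
        assert np.argmin(cost[3]) == 1  # follows its label-1 neighbors
        cost0 = _assignment_cost(X, centers, labels, indptr, indices, 0.0)
        assert cost0[3, 0] == cost0[3, 1]  # pure distance is tied

    def test_k_larger_than_n_rejected(self):
        df = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            spatially_regularized_kmeans(df, None, k=5, lam=0.0, seed=0)


class TestIdentifyMethods:
    def test_cc_recovers_pure_blocks(self, two_block_table):
        res = identify_cc(two_block_table, k=2, m=5, seed=0)
        truth = pd.Series([0] * 40 + [1] * 40, index=two_block_table.cell_ids)
        assert nmi(res.labeling, truth) == pytest.approx(1.0)

    def test_cc_m1_k_equals_vocab_recovers_cts(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.uniform(0, 50, (60, 2)), list("ab" * 30))
        res = identify_cc(t, k=2, m=1, seed=0)
        truth = pd.Series([0, 1] * 30, index=t.cell_ids)
        assert nmi(res.labeling, truth) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["cc", "cne", "cfidf"])
    def test_same_seed_same_labeling(self, method, two_block_table):
        kwargs = {
            "cc": dict(k=2, m=5),
            "cne": dict(k=2, perp=5.0),
            "cfidf": dict(k=2, eps=np.inf, r=1.0),
        }[method]
        fn = {"cc": identify_cc, "cne": identify_cne, "cfidf": identify_cfidf}[method]
        a = fn(two_block_table, seed=3, **kwargs).labeling
        b = fn(two_block_table, seed=3, **kwargs).labeling
        assert a.equals(b)

    def test_cne_disjoint_vocabulary_regions_fully_recovered(self, two_block_table):
        # two spatially separated regions with disjoint CT vocabularies:
        # kernel support never crosses regions, so recovery is exact
        res = identify_cne(two_block_table, k=2, perp=10.0, seed=0)
        truth = pd.Series([0] * 40 + [1] * 40, index=two_block_table.cell_ids)
        assert nmi(res.labeling, truth) == pytest.approx(1.0)

    def test_perp_sweep_stable(self):
        cells, _ = simulate_tissue(SyntheticTissueSpec(n_cells=800, n_cns=3, seed=9))
        labelings = [
            identify_cne(cells, k=3, perp=p, seed=0).labeling
            for p in (10.0, 15.0, 20.0)
        ]
        for i in range(len(labelings)):
            for j in range(i + 1, len(labelings)):
                assert nmi(labelings[i], labelings[j]) > 0.5

    def test_mean_instance_size_nondecreasing_in_perp(self):
        from cnkit.evaluate import mean_cn_instance_size
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(5):
            cells, _ = simulate_tissue(
                SyntheticTissueSpec(n_cells=700, n_cns=3, seed=20 + seed)
            )
            graphs = build_delaunay_graphs(cells)
            sizes = [
                mean_cn_instance_size(
                    identify_cne(cells, k=3, perp=p, seed=seed).labeling, graphs
                )
                for p in (5.0, 10.0, 20.0)
            ]
            rhos.append(spearmanr([5, 10, 20], sizes).statistic)
        assert np.median(rhos) > 0

    def test_lambda_smoothing_coarsens(self):
        from cnkit.evaluate import mean_cn_instance_size

        gains = []
        for seed in range(3):
            cells, _ = simulate_tissue(
                SyntheticTissueSpec(n_cells=700, n_cns=3, seed=40 + seed)
            )
            graphs = build_delaunay_graphs(cells)
            s_reg = mean_cn_instance_size(
                identify_cne(cells, k=3, perp=10.0, lam=0.25, seed=seed).labeling, graphs
            )
            s_plain = mean_cn_instance_size(
                identify_cne(cells, k=3, perp=10.0, lam=0.0, seed=seed).labeling, graphs
            )
            gains.append(s_reg - s_plain)
        assert np.median(gains) >= 0


class TestCFIDF:
    def test_edge_weight_small_distance_limit(self):
        # two tight cells plus one distant: near-zero normalized distance
        t = make_table([(0, 0), (1e-9, 0), (1, 0)], "aab")
        g = cfidf_weighted_graph(t, "img0", eps=np.inf)
        assert g.weights.max() == pytest.approx(np.log2(1 / 0.005), abs=1e-3)

    def test_edge_weight_at_known_normalized_distance(self):
        # distances {1,1,2}: mean 4/3, so the unit edges sit at d_hat = 3/4
        t = make_table([(0, 0), (1, 0), (2, 0)], "aab")
        g = cfidf_weighted_graph(t, "img0", eps=np.inf)
        assert g.weights.max() == pytest.approx(np.log2(1 / (0.005 + 0.75)))

    def test_edge_at_mean_distance_has_negative_raw_weight_clipped(self):
        # a two-cell image puts its only edge exactly at d_hat = 1, whose
        # raw weight log2(1/1.005) is negative and is clipped to zero
        t = make_table([(0, 0), (1, 0)], "ab")
        with pytest.warns(UserWarning, match="clipped"):
            g = cfidf_weighted_graph(t, "img0", eps=np.inf)
        assert g.weights[0] == 0.0

    def test_weights_monotone_in_distance(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.uniform(0, 10, (30, 2)), ["a"] * 30)
        g = cfidf_weighted_graph(t, "img0", eps=np.inf)
        coo = g.to_scipy().tocoo()
        xy = t.df[["x", "y"]].to_numpy()
        d = np.linalg.norm(xy[coo.row] - xy[coo.col], axis=1)
        order = np.argsort(d)
        assert (np.diff(coo.data[order]) <= 1e-12).all()

    def test_planted_communities_recovered(self, two_block_table):
        res = identify_cfidf(two_block_table, k=2, eps=np.inf, r=1.0, seed=0)
        truth = pd.Series([0] * 40 + [1] * 40, index=two_block_table.cell_ids)
        assert nmi(res.labeling, truth) == pytest.approx(1.0)

    def test_too_few_communities_suggests_higher_resolution(self):
        t = make_table([(0, 0), (1, 0), (0, 1), (1, 1)], "aabb")
        with pytest.raises(ValueError, match="resolution"):
            identify_cfidf(t, k=4, eps=np.inf, r=0.0001, seed=0)
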