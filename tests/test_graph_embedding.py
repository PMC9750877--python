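"""Normalization arithmetic, covariate regression, the mean + 1.5 s.d. kNN
edge rule (against brute force), the temporal graph contract, and the
delegated clustering/connectivity calls."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from sctotal import graph_embedding as ge
from sctotal.synthetic_data import SyntheticConfig, simulate_technologies


def expr_adata(X, obs_names=None):
    X = np.asarray(X, dtype=float)
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=obs_names or [f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])]),
    )


class TestNormalize:
    def test_counts_scaled_to_target_then_logged(self):
        adata = expr_adata([[50, 4950], [10, 90]])
        out = ge.normalize(adata)
        assert out.X[0, 0] == pytest.approx(np.log1p(100.0))
        linear = np.expm1(out.X)
        assert linear.sum(axis=1) == pytest.approx([1e4, 1e4])

    def test_all_zero_gene_stays_zero(self):
        adata = expr_adata([[5, 0], [7, 0]])
        out = ge.normalize(adata)
        assert (out.X[:, 1] == 0).all()

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            ge.normalize(expr_adata([[0, 0], [1, 2]]))


class TestHVG:
    def test_excluded_genes_absent_and_subset_property(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(rng.lognormal(0.0, 1.0, size=200), size=(300, 200))
        adata = ge.normalize(expr_adata(X))
        hvg_all = ge.select_hvg(adata)
        excluded = list(hvg_all[:3])
        hvg_sub = ge.select_hvg(adata, exclude=excluded)
        assert not set(excluded) & set(hvg_sub)
        assert set(hvg_sub) <= set(hvg_all)

    def test_planted_high_variance_genes_rank_in_top_set(self):
        rng = np.random.default_rng(1)
        n_cells, n_genes = 400, 500
        # nulls span a range of means so the planted genes are z-scored
        # against same-mean constant-rate genes, not against each other
        base = rng.lognormal(0.7, 0.7, size=n_genes)
        lam = np.tile(base, (n_cells, 1))
        hot = rng.random(n_cells) < 0.5
        lam[np.ix_(hot, np.arange(10))] *= 3.4  # bimodal -> high dispersion
        lam[np.ix_(~hot, np.arange(10))] *= 0.2
        adata = ge.normalize(expr_adata(rng.poisson(lam)))
        hvg = ge.select_hvg(adata)
        planted = {f"g{j}" for j in range(10)}
        assert len(planted & set(hvg)) >= 9


class TestRegression:
    def test_residuals_uncorrelated_with_covariates(self):
        rng = np.random.default_rng(2)
        n = 200
        cov = pd.DataFrame({"depth": rng.normal(size=n)}, index=[f"c{i}" for i in range(n)])
        X = 2.0 * cov["depth"].to_numpy()[:, None] + rng.normal(size=(n, 30))
        adata = expr_adata(X, obs_names=list(cov.index))
        out = ge.regress_covariates(adata, cov)
        for j in range(out.n_vars):
            r = np.corrcoef(out.X[:, j], cov["depth"])[0, 1]
            assert abs(r) < 1e-8

    def test_orthogonal_covariate_only_rescales(self):
        rng = np.random.default_rng(3)
        n = 400
        cov = pd.DataFrame({"z": np.tile([1.0, -1.0], n // 2)}, index=[f"c{i}" for i in range(n)])
        feature = np.repeat([0.0, 1.0], n // 2)  # orthogonal to z by construction
        adata = expr_adata(feature[:, None], obs_names=list(cov.index))
        out = ge.regress_covariates(adata, cov)
        expected = (feature - feature.mean()) / feature.std(ddof=1)
        assert out.X[:, 0] == pytest.approx(expected, abs=1e-8)

    def test_constant_feature_becomes_zero(self):
        cov = pd.DataFrame({"z": [0.1, 0.4, -0.2, 0.9]}, index=list("abcd"))
        adata = expr_adata(np.full((4, 1), 3.0), obs_names=list("abcd"))
        out = ge.regress_covariates(adata, cov)
        assert (out.X == 0).all()


class TestKnnGraph:
    def test_edge_rule_on_worked_distances(self):
        # 4 collinear points, k=1: candidate NN distances {1, 1, 1, 10};
        # threshold = mean + 1.5 sd = 10.0 (n-1 denominator) and the rule is
        # strict, so the length-10 edge is dropped
        coords = np.array([[0.0], [1.0], [2.0], [12.0]])
        g = ge.build_knn_graph(coords, k=1)
        assert g.threshold == pytest.approx(10.0)
        assert g.n_removed_edges == 1
        assert 3 not in set(g.undirected_edges["source"]) | set(g.undirected_edges["target"])

    def test_every_retained_edge_satisfies_strict_threshold(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(150, 8))
        g = ge.build_knn_graph(coords, k=10)
        assert (g.directed_edges["distance"] < g.threshold).all()
        flat = []
        d = cdist(coords, coords, metric="cityblock")
        np.fill_diagonal(d, np.inf)
        for i in range(150):
            flat.extend(np.sort(d[i])[:10])
        flat = np.asarray(flat)
        assert g.threshold == pytest.approx(flat.mean() + 1.5 * flat.std(ddof=1))
        assert g.n_candidate_edges == 1500

    def test_neighbor_sets_match_brute_force(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(200, 6))
        g = ge.build_knn_graph(coords, k=10)
        d = cdist(coords, coords, metric="cityblock")
        np.fill_diagonal(d, np.inf)
        got = g.directed_edges.groupby("source")["target"].apply(set)
        for i in range(200):
            nn = set(np.argsort(d[i], kind="stable")[:10])
            kept = {j for j in nn if d[i, j] < g.threshold}
            assert got.get(i, set()) == kept

    def test_equidistant_points_keep_all_edges(self):
        # vertices of a regular simplex: all pairwise distances equal, sd = 0
        coords = np.eye(5)
        g = ge.build_knn_graph(coords, k=4)
        assert g.n_removed_edges == 0
        assert len(g.directed_edges) == 20

    def test_k_not_smaller_than_n_rejected(self):
        with pytest.raises(ValueError):
            ge.build_knn_graph(np.zeros((5, 2)), k=5)

    def test_permutation_invariance_of_edge_set(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(80, 5))
        names = pd.Index([f"c{i:03d}" for i in range(80)])
        g1 = ge.build_knn_graph(pd.DataFrame(coords, index=names), k=10)
        perm = rng.permutation(80)
        g2 = ge.build_knn_graph(pd.DataFrame(coords[perm], index=names[perm]), k=10)
        e1 = {tuple(r) for r in g1.undirected_edges[["source", "target"]].to_numpy()}
        e2 = {tuple(r) for r in g2.undirected_edges[["source", "target"]].to_numpy()}
        assert e1 == e2


class TestTemporalGraph:
    def _matrices(self, spread=1.0, n=60, seed=7):
        rng = np.random.default_rng(seed)
        out = {}
        for i, tp in enumerate(["E6.5", "E7.5", "E8.5", "E9.5"]):
            X = rng.normal(i * spread, 1.0, size=(n, 12))
            out[tp] = pd.DataFrame(X, index=[f"{tp}|{j}" for j in range(n)])
        return out

    def test_no_edge_spans_more_than_one_timepoint_step(self):
        mats = self._matrices(spread=0.5)
        g = ge.build_temporal_graph(mats, list(mats), k=15)
        order = {tp: i for i, tp in enumerate(mats)}
        steps = [
            abs(order[s.split("|")[0]] - order[t.split("|")[0]])
            for s, t in zip(g.undirected_edges["source"], g.undirected_edges["target"])
        ]
        assert max(steps) == 1  # adjacent links exist, none longer
        # earliest timepoint: outgoing edges stay within E6.5
        first = g.directed_edges[g.directed_edges["source"].str.startswith("E6.5")]
        assert first["target"].str.startswith("E6.5").all()

    def test_separated_persistent_clusters_stay_disconnected(self):
        rng = np.random.default_rng(8)
        mats = {}
        for i, tp in enumerate(["E6.5", "E7.5"]):
            a = rng.normal(0.0, 0.3, size=(40, 6))
            b = rng.normal(50.0, 0.3, size=(40, 6))
            mats[tp] = pd.DataFrame(
                np.vstack([a, b]),
                index=[f"{tp}|a{j}" for j in range(40)] + [f"{tp}|b{j}" for j in range(40)],
            )
        g = ge.build_temporal_graph(mats, list(mats), k=10)
        crosses = [
            ("|a" in s) != ("|a" in t)
            for s, t in zip(g.undirected_edges["source"], g.undirected_edges["target"])
        ]
        assert not any(crosses)


@pytest.fixture(scope="module")
def planted():
    cfg = SyntheticConfig(seed=7)
    techs, _ = simulate_technologies(cfg)
    adata = techs["total"]
    norm = ge.normalize(adata)
    reg = ge.regress_covariates(norm, ["total_counts"])
    coords = ge.run_pca(reg, 30, seed=0)
    graph = ge.build_knn_graph(pd.DataFrame(coords, index=adata.obs_names), k=10)
    return adata, graph


class TestClusteringContracts:
    def test_leiden_recovers_planted_clusters(self, planted):
        adata, graph = planted
        _, labels = ge.embed_and_cluster(graph, with_umap=False, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth = adata.obs["cluster"].loc[labels.index]
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_same_seed_gives_identical_labels(self, planted):
        _, graph = planted
        _, l1 = ge.embed_and_cluster(graph, with_umap=False, seed=3)
        _, l2 = ge.embed_and_cluster(graph, with_umap=False, seed=3)
        assert l1.equals(l2)

    def test_disconnected_components_give_separate_clusters(self):
        a = np.random.default_rng(9).normal(0, 0.2, size=(30, 3))
        coords = np.vstack([a, a + 100.0])
        g = ge.build_knn_graph(coords, k=5)
        _, labels = ge.embed_and_cluster(g, with_umap=False, seed=0)
        assert labels.nunique() >= 2
        assert labels.iloc[:30].nunique() * labels.iloc[30:].nunique() >= 1
        assert set(labels.iloc[:30]) & set(labels.iloc[30:]) == set()

    def test_paga_and_fallback_agree_in_ranking(self, planted):
        adata, graph = planted
        labels = adata.obs["cluster"].loc[graph.nodes]
        paga = ge.paga_connectivity(graph, labels)
        fallback = ge.edge_connectivity(graph, labels)
        fallback = fallback.loc[paga.index, paga.columns]
        assert np.allclose(paga.values, paga.values.T)
        assert np.allclose(fallback.values, fallback.values.T)
        iu = np.triu_indices(len(paga), 1)
        from scipy.stats import spearmanr

        rho = spearmanr(paga.values[iu], fallback.values[iu]).statistic
        if np.isnan(rho):  # all-equal connectivities carry no ranking signal
            assert np.allclose(paga.values[iu], paga.values[iu][0])
        else:
            assert rho >= 0.9

    def test_disconnected_clusters_have_zero_connectivity(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.2, size=(25, 3))
        coords = np.vstack([a, a + 100.0])
        g = ge.build_knn_graph(coords, k=5)
        labels = pd.Series(["A"] * 25 + ["B"] * 25, index=g.nodes)
        conn = ge.edge_connectivity(g, labels)
        assert conn.loc["A", "B"] == 0.0
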