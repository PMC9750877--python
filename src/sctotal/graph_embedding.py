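"""Normalization, covariate regression, and the custom Manhattan kNN graph.

The graph rule: for each cell take its k nearest neighbors (Manhattan metric
in PCA space); an outgoing edge i->j survives only if its length is strictly
below mean + 1.5 s.d. of *all* k*n candidate nearest-neighbor distances
(global statistic, n-1 s.d. denominator).  Isolated cells are dropped and the
directed graph is symmetrized by union.  The temporal variant connects each
cell to its 30 nearest neighbors among cells of the same and the previous
timepoint, projected into the later timepoint's PCA basis, so no edge ever
spans more than one timepoint step.

Embedding (UMAP) and clustering (Leiden, resolution 1) are thin, seeded
contracts over the standard implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "CellGraph",
    "normalize",
    "select_hvg",
    "regress_covariates",
    "run_pca",
    "build_knn_graph",
    "build_temporal_graph",
    "embed_and_cluster",
    "paga_connectivity",
    "edge_connectivity",
]

NORM_TARGET = 1e4


def normalize(adata: ad.AnnData, copy: bool = True) -> ad.AnnData:
    """Library-size normalize to 10^4 transcripts per cell and log-transform
    with pseudo-count 1.  Rejects zero-total cells."""
    counts = np.asarray(adata.X, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("zero-total cells cannot be normalized; filter them first")
    out = adata.copy() if copy else adata
    out.layers["counts"] = counts.astype(np.int64)
    linear = counts / totals[:, None] * NORM_TARGET
    out.layers["normalized"] = linear  # linear scale, for fold-change rules
    out.X = np.log1p(linear)
    out.obs["total_counts"] = totals
    return out


def select_hvg(
    adata: ad.AnnData,
    min_mean: float = 0.0125,
    max_mean: float = 5.0,
    min_disp: float = 0.5,
    exclude: list[str] | None = None,
) -> pd.Index:
    """Dispersion-based highly variable gene selection (delegated to scanpy),
    restricted to the stated mean-log-expression window, minus an exclusion
    list (cell-cycle genes)."""
    import scanpy as sc

    tmp = adata.copy()
    sc.pp.highly_variable_genes(
        tmp, min_mean=min_mean, max_mean=max_mean, min_disp=min_disp, flavor="seurat"
    )
    hvg = tmp.var_names[tmp.var["highly_variable"]]
    if exclude:
        hvg = hvg.difference(pd.Index(exclude), sort=False)
    return hvg


def regress_covariates(
    adata: ad.AnnData, covariates: pd.DataFrame | list[str], copy: bool = True
) -> ad.AnnData:
    """Regress per-cell covariates out of each feature, then z-scale.

    Per feature, values are replaced by the residuals of an ordinary
    least-squares fit (with intercept) on the covariate matrix, then scaled to
    zero mean and unit variance; constant features become zero vectors.
    """
    if isinstance(covariates, list):
        cov = adata.obs[covariates].to_numpy(dtype=float)
    else:
        cov = covariates.reindex(adata.obs_names).to_numpy(dtype=float)
    X = np.asarray(adata.X, dtype=float)
    design = np.column_stack([np.ones(len(X)), cov])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (resid - resid.mean(axis=0)) / sd, 0.0)
    out = adata.copy() if copy else adata
    out.X = z
    return out


def run_pca(adata: ad.AnnData, n_components: int = 50, seed: int = 0) -> np.ndarray:
    """PCA coordinates (50 components by default, 20 for very small datasets)."""
    from sklearn.decomposition import PCA

    n_components = min(n_components, adata.n_obs - 1, adata.n_vars)
    model = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coords = model.fit_transform(np.asarray(adata.X, dtype=float))
    adata.obsm["X_pca"] = coords
    adata.uns["pca_model"] = model
    return coords


@dataclass
class CellGraph:
    """Directed kNN edges after the global distance filter, plus the derived
    undirected (union) edge list over retained (non-isolated) nodes."""

    nodes: pd.Index
    directed_edges: pd.DataFrame  # source, target, distance
    undirected_edges: pd.DataFrame  # source, target, distance (source < target)
    threshold: float
    n_candidate_edges: int
    n_removed_edges: int

    def igraph(self):
        import igraph as ig

        index = {n: i for i, n in enumerate(self.nodes)}
        edges = [
            (index[s], index[t])
            for s, t in zip(self.undirected_edges["source"], self.undirected_edges["target"])
        ]
        g = ig.Graph(n=len(self.nodes), edges=edges)
        g.vs["name"] = list(self.nodes)
        g.es["distance"] = list(self.undirected_edges["distance"])
        return g


def _knn_candidates(
    coords: np.ndarray, query: np.ndarray, k: int, metric: str = "cityblock"
) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbors of each query row among ``coords`` rows, ties
    broken by index, self-matches excluded when the arrays are identical."""
    d = cdist(query, coords, metric=metric)
    same = query is coords
    if same:
        np.fill_diagonal(d, np.inf)
    # stable argsort on distance then index for deterministic ties
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    dist = np.take_along_axis(d, nn, axis=1)
    return nn, dist


def build_knn_graph(
    coords: np.ndarray | pd.DataFrame,
    k: int = 10,
    metric: str = "cityblock",
    names: pd.Index | None = None,
) -> CellGraph:
    """Build the filtered directed kNN graph.

    All k*n candidate nearest-neighbor distances define the global threshold
    mean + 1.5 s.d. (n-1 denominator); a candidate edge survives only if its
    distance is strictly below the threshold.  When the s.d. is zero (all
    candidate distances equal) every edge is kept: the filter prunes
    outliers and a zero-spread set has none.  Cells left without any edge are
    removed; the undirected graph is the union of the directed edges.
    """
    if isinstance(coords, pd.DataFrame):
        names = coords.index if names is None else names
        coords = coords.to_numpy(dtype=float)
    n = len(coords)
    if names is None:
        names = pd.Index(np.arange(n))
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")

    nn, dist = _knn_candidates(coords, coords, k, metric)
    flat = dist.ravel()
    sd = flat.std(ddof=1) if flat.size > 1 else 0.0
    threshold = float(flat.mean() + 1.5 * sd)
    keep = dist < threshold if sd > 0 else np.ones_like(dist, dtype=bool)

    src, tgt = np.nonzero(keep)
    directed = pd.DataFrame(
        {
            "source": names[src],
            "target": names[nn[src, tgt]],
            "distance": dist[src, tgt],
        }
    )
    a = np.minimum(directed["source"].to_numpy(), directed["target"].to_numpy())
    b = np.maximum(directed["source"].to_numpy(), directed["target"].to_numpy())
    und = (
        pd.DataFrame({"source": a, "target": b, "distance": directed["distance"]})
        .groupby(["source", "target"], as_index=False, sort=True)["distance"]
        .min()
    )
    connected = pd.Index(np.union1d(und["source"], und["target"]))
    nodes = names[names.isin(connected)]
    return CellGraph(
        nodes=nodes,
        directed_edges=directed.reset_index(drop=True),
        undirected_edges=und,
        threshold=threshold,
        n_candidate_edges=int(dist.size),
        n_removed_edges=int(dist.size - keep.sum()),
    )


def build_temporal_graph(
    coords_by_timepoint: dict[str, pd.DataFrame],
    timepoint_order: list[str] | None = None,
    k: int = 30,
    n_components: int = 50,
    seed: int = 0,
    metric: str = "cityblock",
) -> CellGraph:
    """Temporal master graph across ordered timepoints.

    ``coords_by_timepoint`` maps timepoint -> cells x features matrix
    (normalized expression over a shared feature set).  For each timepoint t,
    cells from t and t-1 are projected into t's PCA basis and each cell of t
    draws directed edges to its k nearest neighbors in that candidate pool
    (earliest timepoint: within-timepoint only).  No distance filter is
    applied; the undirected union is returned.
    """
    from sklearn.decomposition import PCA

    order = timepoint_order or list(coords_by_timepoint)
    directed_rows = []
    all_names: list = []
    for ti, tp in enumerate(order):
        mat = coords_by_timepoint[tp]
        all_names.extend(mat.index)
        pool = [mat] if ti == 0 else [mat, coords_by_timepoint[order[ti - 1]]]
        pool_df = pd.concat(pool)
        n_comp = min(n_components, len(mat) - 1, mat.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
        pca.fit(mat.to_numpy(dtype=float))
        proj_pool = pca.transform(pool_df.to_numpy(dtype=float))
        proj_query = proj_pool[: len(mat)]
        kk = min(k, len(pool_df) - 1)
        d = cdist(proj_query, proj_pool, metric=metric)
        d[np.arange(len(mat)), np.arange(len(mat))] = np.inf  # self within pool
        nn = np.argsort(d, axis=1, kind="stable")[:, :kk]
        dist = np.take_along_axis(d, nn, axis=1)
        pool_names = pool_df.index.to_numpy()
        for i, cell in enumerate(mat.index):
            for j in range(kk):
                directed_rows.append((cell, pool_names[nn[i, j]], dist[i, j]))

    directed = pd.DataFrame(directed_rows, columns=["source", "target", "distance"])
    a = np.minimum(directed["source"].to_numpy(), directed["target"].to_numpy())
    b = np.maximum(directed["source"].to_numpy(), directed["target"].to_numpy())
    und = (
        pd.DataFrame({"source": a, "target": b, "distance": directed["distance"]})
        .groupby(["source", "target"], as_index=False, sort=True)["distance"]
        .min()
    )
    names = pd.Index(all_names)
    connected = pd.Index(np.union1d(und["source"], und["target"]))
    return CellGraph(
        nodes=names[names.isin(connected)],
        directed_edges=directed,
        undirected_edges=und,
        threshold=np.inf,
        n_candidate_edges=len(directed),
        n_removed_edges=0,
    )


def embed_and_cluster(
    graph: CellGraph,
    coords: pd.DataFrame | np.ndarray | None = None,
    resolution: float = 1.0,
    seed: int = 0,
    with_umap: bool = True,
) -> tuple[pd.DataFrame | None, pd.Series]:
    """Leiden clustering on the undirected graph (+ optional UMAP layout).

    A thin, seeded contract over leidenalg and umap-learn: Leiden runs at the
    stated resolution on the union graph with weights 1/(1+d); UMAP embeds
    the PCA coordinates when given.
    """
    import leidenalg

    g = graph.igraph()
    weights = [1.0 / (1.0 + d) for d in g.es["distance"]]
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = pd.Series(
        [str(m) for m in part.membership], index=graph.nodes, name="leiden"
    )
    embedding = None
    if with_umap and coords is not None:
        import umap

        if isinstance(coords, pd.DataFrame):
            coords = coords.loc[graph.nodes].to_numpy(dtype=float)
        model = umap.UMAP(random_state=seed, n_jobs=1)
        emb = model.fit_transform(coords)
        embedding = pd.DataFrame(emb, index=graph.nodes, columns=["umap1", "umap2"])
    return embedding, labels


def edge_connectivity(graph: CellGraph, labels: pd.Series) -> pd.DataFrame:
    """Coarse cluster-connectivity statistic (documented approximation).

    Observed inter-cluster undirected edge count divided by its expectation
    under degree-preserving random mixing (configuration model):
    E[e_ab] = deg_a * deg_b / (2m).  Symmetric; zero for disconnected pairs.
    This is not PAGA; it is a fallback with the same ranking intent.
    """
    lab = labels.reindex(graph.nodes)
    groups = sorted(lab.unique())
    und = graph.undirected_edges
    m = len(und)
    deg = pd.concat([und["source"], und["target"]]).value_counts()
    deg_per_group = {
        g: float(deg.reindex(lab.index[lab == g]).fillna(0).sum()) for g in groups
    }
    obs = pd.DataFrame(0.0, index=groups, columns=groups)
    for s, t in zip(und["source"], und["target"]):
        gs, gt = lab.loc[s], lab.loc[t]
        if gs != gt:
            obs.loc[gs, gt] += 1.0
            obs.loc[gt, gs] += 1.0
    conn = pd.DataFrame(0.0, index=groups, columns=groups)
    for ga in groups:
        for gb in groups:
            if ga == gb:
                continue
            expected = deg_per_group[ga] * deg_per_group[gb] / (2.0 * m)
            conn.loc[ga, gb] = obs.loc[ga, gb] / expected if expected > 0 else 0.0
    return conn


def paga_connectivity(graph: CellGraph, labels: pd.Series) -> pd.DataFrame:
    """Cluster x cluster connectivity via PAGA (delegated to scanpy); falls
    back to :func:`edge_connectivity` if the delegated call is unavailable."""
    try:
        import scanpy as sc

        nodes = graph.nodes
        index = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        from scipy.sparse import coo_matrix

        und = graph.undirected_edges
        rows = [index[s] for s in und["source"]]
        cols = [index[t] for t in und["target"]]
        w = 1.0 / (1.0 + und["distance"].to_numpy())
        conn = coo_matrix(
            (np.concatenate([w, w]), (rows + cols, cols + rows)), shape=(n, n)
        ).tocsr()
        adata = ad.AnnData(
            X=np.zeros((n, 1)),
            obs=pd.DataFrame(
                {"groups": pd.Categorical(labels.reindex(nodes))},
                index=pd.Index(nodes, name="cell"),
            ),
        )
        adata.obsp["connectivities"] = conn
        adata.obsp["distances"] = conn
        adata.uns["neighbors"] = {
            "connectivities_key": "connectivities",
            "distances_key": "distances",
            "params": {"n_neighbors": 10, "method": "umap"},
        }
        sc.tl.paga(adata, groups="groups")
        mat = np.asarray(adata.uns["paga"]["connectivities"].todense())
        cats = list(adata.obs["groups"].cat.categories)
        return pd.DataFrame(mat, index=cats, columns=cats)
    except Exception:
        return edge_connectivity(graph, labels)
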