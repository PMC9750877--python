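"""Cross-technology cluster transfer and per-cluster marker comparison.

Two technologies measuring the same biological sample are embedded in one
PCA space (after regressing out technology and depth).  For a reference
cluster, the background distribution is the first-nearest-neighbor Manhattan
distance of each of its cells into the target technology.  Each target cell
is then assigned the cluster of its nearest reference cell with a transfer
score: the fraction of background distances at least as large as the cell's
own distance (empirical survival function).  A cell sitting closer than most
of the cluster's background scores near 1; a cell farther than all of it
scores 0 and is excluded as unreliable.

Equivalent clusters are groups of cells with identical cluster assignments
in both transfer directions, the unit at which marker genes of the two
technologies are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats

__all__ = [
    "TransferAssignment",
    "EquivalentCluster",
    "background_distances",
    "transfer_score",
    "assign_cells",
    "equivalent_clusters",
    "de_genes",
]


@dataclass(frozen=True)
class TransferAssignment:
    cell: str
    cluster: str
    distance: float
    score: float
    background_size: int


@dataclass(frozen=True)
class EquivalentCluster:
    cluster_id: str
    reference_label: str
    target_label: str
    members_per_tech: dict[str, tuple[str, ...]]
    germ_layer: str | None = None


def background_distances(
    reference_coords: pd.DataFrame,
    target_coords: pd.DataFrame,
    metric: str = "cityblock",
) -> np.ndarray:
    """One first-nearest-neighbor distance per reference-cluster cell into
    the target technology."""
    if len(target_coords) == 0:
        raise ValueError("target technology has no cells")
    d = cdist(
        reference_coords.to_numpy(dtype=float),
        target_coords.to_numpy(dtype=float),
        metric=metric,
    )
    return d.min(axis=1)


def transfer_score(
    distance: float, background: np.ndarray, mode: str = "survival"
) -> float:
    """Score of a cell-to-reference distance against a background sample.

    ``survival`` (default): fraction of background distances >= d, so small
    distances relative to background give scores near 1 and low-score cells
    (farther than the background) are the unreliable ones to exclude.  The
    alternative ``ecdf`` orientation (fraction <= d) is available for
    comparison.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background sample is empty")
    if mode == "survival":
        return float((bg >= distance).mean())
    if mode == "ecdf":
        return float((bg <= distance).mean())
    raise ValueError(f"unknown mode {mode!r}")


def assign_cells(
    target_coords: pd.DataFrame,
    reference_coords: pd.DataFrame,
    reference_labels: pd.Series,
    score_min: float = 0.05,
    metric: str = "cityblock",
    mode: str = "survival",
) -> pd.DataFrame:
    """Assign each target cell the cluster of its nearest reference cell.

    The transfer score is computed against the assigned cluster's background
    (first-NN distances of that cluster's cells into the target technology);
    cells scoring below ``score_min`` are dropped.  Nearest-neighbor ties are
    broken by reference cell order (cell id).
    """
    labels = reference_labels.reindex(reference_coords.index)
    backgrounds = {
        cluster: background_distances(
            reference_coords.loc[labels.index[labels == cluster]], target_coords, metric
        )
        for cluster in labels.unique()
    }
    d = cdist(
        target_coords.to_numpy(dtype=float),
        reference_coords.to_numpy(dtype=float),
        metric=metric,
    )
    nn = np.argmin(d, axis=1)  # first occurrence wins ties -> cell-id order
    rows = []
    for i, cell in enumerate(target_coords.index):
        cluster = labels.iloc[nn[i]]
        dist = float(d[i, nn[i]])
        score = transfer_score(dist, backgrounds[cluster], mode=mode)
        if score >= score_min:
            rows.append(
                {
                    "cell": cell,
                    "cluster": cluster,
                    "distance": dist,
                    "score": score,
                    "background_size": len(backgrounds[cluster]),
                }
            )
    return pd.DataFrame(rows, columns=["cell", "cluster", "distance", "score", "background_size"])


def equivalent_clusters(
    native_labels: dict[str, pd.Series],
    transferred_labels: dict[str, pd.DataFrame],
    min_cells: int = 1,
    germ_layer_annotation: pd.Series | None = None,
    reference_tech: str | None = None,
) -> list[EquivalentCluster]:
    """Intersect the two directed transfers into equivalent clusters.

    ``native_labels[tech]`` holds each technology's own cluster labels;
    ``transferred_labels[tech]`` the assignment table of the *other*
    technology's clusters onto tech's cells.  A cell supports the label pair
    (own cluster, transferred cluster); an equivalent cluster is a pair
    supported by at least ``min_cells`` cells in *both* technologies.  The
    germ-layer annotation (reference-technology cluster -> layer) is attached
    by majority vote over member cells when provided.
    """
    techs = list(native_labels)
    if len(techs) != 2:
        raise ValueError("exactly two technologies are required")
    pair_members: dict[tuple[str, str], dict[str, list[str]]] = {}
    for ti, tech in enumerate(techs):
        own = native_labels[tech]
        transferred = transferred_labels[tech].set_index("cell")["cluster"]
        for cell in transferred.index:
            if cell not in own.index:
                continue
            # orient every pair as (first tech's label, second tech's label)
            pair = (
                (own.loc[cell], transferred.loc[cell])
                if ti == 0
                else (transferred.loc[cell], own.loc[cell])
            )
            pair_members.setdefault(pair, {t: [] for t in techs})[tech].append(cell)

    out = []
    ref = reference_tech or techs[0]
    for i, (pair, members) in enumerate(sorted(pair_members.items())):
        if any(len(members[t]) < min_cells for t in techs):
            continue
        layer = None
        if germ_layer_annotation is not None:
            ref_label = pair[0] if ref == techs[0] else pair[1]
            layer = germ_layer_annotation.get(ref_label)
        out.append(
            EquivalentCluster(
                cluster_id=f"EQ{len(out):03d}",
                reference_label=pair[0],
                target_label=pair[1],
                members_per_tech={t: tuple(members[t]) for t in techs},
                germ_layer=layer,
            )
        )
    return out


def de_genes(
    adata: ad.AnnData,
    group_a,
    group_b,
    log2fc_min: float | None = None,
    p_max: float | None = None,
    layer: str | None = None,
) -> pd.DataFrame:
    """Differential expression between two cell groups.

    Per feature: a two-sided Welch t-test plus a log2 fold change computed
    with a pseudo-count equal to the minimum positive mean expression across
    features, log2((meanA + c) / (meanB + c)).  The table carries mean, s.d.
    and fraction of expressing cells per group; features that are all-zero in
    both groups are excluded (the test is undefined there).  P values are
    uncorrected, with a BH-adjusted column alongside; when both thresholds
    are given, passing features are flagged ``selected``.
    """
    group_a = pd.Index(group_a)
    group_b = pd.Index(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    X = adata.layers[layer] if layer else adata.X
    X = np.asarray(X, dtype=float)
    ia = adata.obs_names.get_indexer(group_a)
    ib = adata.obs_names.get_indexer(group_b)
    if (ia < 0).any() or (ib < 0).any():
        raise KeyError("group contains cells absent from the matrix")
    A, B = X[ia], X[ib]

    nonzero = (A.sum(axis=0) + B.sum(axis=0)) > 0
    A, B = A[:, nonzero], B[:, nonzero]
    features = adata.var_names[nonzero]

    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    all_means = np.concatenate([mean_a, mean_b])
    positive = all_means[all_means > 0]
    pseudo = float(positive.min()) if positive.size else 1.0
    log2fc = np.log2((mean_a + pseudo) / (mean_b + pseudo))

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)

    from statsmodels.stats.multitest import multipletests

    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "sd_a": A.std(axis=0, ddof=1),
            "sd_b": B.std(axis=0, ddof=1),
            "frac_expressing_a": (A > 0).mean(axis=0),
            "frac_expressing_b": (B > 0).mean(axis=0),
            "log2fc": log2fc,
            "t_stat": t,
            "pval": p,
            "pval_adj": padj,
        },
        index=pd.Index(features, name="feature"),
    )
    if log2fc_min is not None and p_max is not None:
        table["selected"] = (table["log2fc"] > log2fc_min) & (table["pval"] < p_max)
    return table.sort_values("pval")
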