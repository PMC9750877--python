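"""End-to-end orchestration of the synthetic study.

One call runs generate -> barcode calling -> depletion/assignment/counting ->
QC -> cell cycle -> graph/clustering -> cross-technology transfer ->
splicing statistics on a seeded synthetic experiment, returning every
intermediate table.  The run is deterministic given the config: a digest of
the serialized outputs is byte-identical across invocations with the same
seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Any

import anndata as ad
import numpy as np
import pandas as pd

from . import (
    barcodes as bc,
    cell_cycle as cc,
    feature_counting as fc,
    graph_embedding as ge,
    label_transfer as lt,
    qc,
    splicing as sp,
)
from .synthetic_data import (
    SyntheticConfig,
    make_annotation,
    simulate_reads,
    simulate_splice_counts,
    simulate_technologies,
)


def end_to_end_config(seed: int = 0) -> SyntheticConfig:
    """Scaled-down study conditions for a full pipeline run on one CPU.

    Depth and population sizes are reduced from the generator defaults (see
    the methods note); the knee valley sits near log10 = 2.1 here.
    """
    return SyntheticConfig(
        seed=seed,
        n_real_cells=80,
        n_ambient_barcodes=500,
        cell_log10_reads_mean=2.9,
        cell_log10_reads_sd=0.12,
        ambient_log10_reads_mean=1.3,
        ambient_log10_reads_sd=0.25,
        s_phase_fraction=0.65,
        error_rate=0.005,
        doublet_fraction=0.0,
    )


@dataclass
class PipelineResult:
    """Every artifact of one end-to-end run."""

    config: SyntheticConfig
    threshold_log10: float
    accepted_barcodes: pd.Index
    depletion_report: dict
    matrix: ad.AnnData
    intronic_fraction: pd.Series
    histone_scores: pd.Series
    s_phase_calls: pd.Series
    cluster_labels: pd.Series
    transfer: pd.DataFrame
    disn_table: pd.DataFrame
    snm_table: pd.DataFrame
    truth: Any

    def digest(self) -> str:
        """SHA-256 over the serialized outputs (byte-identity check)."""
        h = hashlib.sha256()
        h.update(f"{self.threshold_log10:.12g}".encode())
        h.update(",".join(self.accepted_barcodes).encode())
        h.update(repr(sorted(self.depletion_report.items())).encode())
        h.update(np.ascontiguousarray(self.matrix.layers["spliced"]).tobytes())
        h.update(np.ascontiguousarray(self.matrix.layers["unspliced"]).tobytes())
        for series in (
            self.intronic_fraction,
            self.histone_scores,
            self.s_phase_calls,
            self.cluster_labels,
        ):
            h.update(series.to_csv().encode())
        h.update(self.transfer.to_csv().encode())
        h.update(self.disn_table.to_csv().encode())
        h.update(self.snm_table.to_csv().encode())
        return h.hexdigest()


def run_pipeline(config: SyntheticConfig | None = None, seed: int = 0) -> PipelineResult:
    """Run the whole synthetic study at the given seed."""
    config = config if config is not None else end_to_end_config(seed)
    annotation = make_annotation(config)
    reads, truth = simulate_reads(annotation, config)

    # ---- barcode calling on the observed (error-containing) stream
    observed = reads["barcode"].value_counts().sort_index()
    hist = bc.BarcodeHistogram(observed)
    threshold = bc.knee_threshold(hist)
    accepted = bc.accept_barcodes(observed, threshold).sort_values()
    whitelist = bc.Whitelist(tuple(accepted), max_distance=2)
    merged = {b: bc.merge_barcodes(b, whitelist) for b in observed.index}
    reads = reads.assign(cell=reads["barcode"].map(merged))
    cell_reads = reads[reads["cell"].notna()].drop(columns=["barcode"]).rename(
        columns={"cell": "barcode"}
    )

    # ---- depletion, assignment, UFI propagation, counting
    survivors, depletion = fc.deplete_rrna(cell_reads, annotation.rrna_intervals())
    assigned = fc.assign_reads(survivors, annotation)
    assigned = fc.propagate_unspliced(assigned)
    matrix = fc.count_molecules(assigned, annotation, cells=list(accepted))
    n_reads = survivors.groupby("barcode").size().reindex(matrix.obs_names, fill_value=0)
    matrix.obs["n_reads"] = n_reads

    # ---- QC summaries and cell-cycle calls
    intronic = fc.intronic_fraction(matrix)
    scores = cc.histone_score(matrix)
    s_calls = cc.call_s_phase(scores, threshold=35)

    # ---- expression graph and clustering on the counted matrix
    expressed = np.asarray(matrix.X.sum(axis=0)).ravel() > 0
    sub = matrix[:, expressed].copy()
    norm = ge.normalize(sub)
    reg = ge.regress_covariates(norm, ["total_counts"])
    coords = ge.run_pca(reg, n_components=20, seed=config.seed)
    graph = ge.build_knn_graph(
        pd.DataFrame(coords, index=sub.obs_names), k=10
    )
    _, labels = ge.embed_and_cluster(graph, with_umap=False, seed=config.seed)

    # ---- cross-technology transfer on the planted clusters
    techs, _ = simulate_technologies(config)
    A, B = techs["total"], techs["capture"]
    both = ad.concat({"total": A, "capture": B}, label="tech")
    both.obs_names = list(A.obs_names) + list(B.obs_names)
    normT = ge.normalize(both)
    normT.obs["is_total"] = (normT.obs["tech"] == "total").astype(float)
    regT = ge.regress_covariates(normT, ["total_counts", "is_total"])
    coordsT = ge.run_pca(regT, n_components=30, seed=config.seed)
    cv = pd.DataFrame(coordsT[: A.n_obs], index=A.obs_names)
    ct = pd.DataFrame(coordsT[A.n_obs:], index=B.obs_names)
    transfer = lt.assign_cells(ct, cv, A.obs["cluster"], score_min=0.05)

    # ---- splicing statistics on planted nodes
    spec = {}
    for n in range(20):
        spec[(f"null{n:02d}", "a")] = 0.5
        spec[(f"null{n:02d}", "b")] = 0.5
    for n in range(10):
        spec[(f"hit{n:02d}", "a")] = 0.2
        spec[(f"hit{n:02d}", "b")] = 0.6
    inc, exc, splice_truth = simulate_splice_counts(
        spec, {"a": 120, "b": 120}, reads_per_node=20, seed=config.seed
    )
    clusters = pd.Series(splice_truth.cell_cluster["splice"])
    disns = sp.call_disns(
        inc, exc, clusters, "a", "b", n_repetitions=10, dpsi_min=0.1, seed=config.seed
    )
    disn_table = pd.DataFrame(
        {
            "node": [r.node for r in disns],
            "dpsi_mean": [r.dpsi_mean for r in disns],
            "cdf_beta": [r.cdf_beta for r in disns],
            "is_disn": [r.is_disn for r in disns],
        }
    )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    bulk_rows, bulk_cluster = [], []
    for cl in ("a", "b"):
        cells = clusters.index[clusters == cl]
        for rep in range(10):
            for bulk in sp.make_pseudobulks(cells, n_bulks=3, max_cells=40, seed=rng):
                bulk_rows.append(
                    (inc.loc[bulk].sum(axis=0), exc.loc[bulk].sum(axis=0))
                )
                bulk_cluster.append(cl)
    bulk_inc = pd.DataFrame([r[0] for r in bulk_rows]).reset_index(drop=True)
    bulk_exc = pd.DataFrame([r[1] for r in bulk_rows]).reset_index(drop=True)
    bulk_psi = sp.psi_table(bulk_inc, bulk_exc, min_reads=10)
    snms = sp.call_snms(
        bulk_psi,
        pd.Series(bulk_cluster),
        min_quantified_bulks=50,
    )
    snm_table = pd.DataFrame(
        {
            "node": [r.node for r in snms],
            "cluster": [r.cluster for r in snms],
            "mean_difference": [r.mean_difference for r in snms],
            "is_snm": [r.is_snm for r in snms],
        }
    )

    truth.node_psi = dict(splice_truth.node_psi)
    return PipelineResult(
        config=config,
        threshold_log10=threshold,
        accepted_barcodes=pd.Index(accepted),
        depletion_report=depletion,
        matrix=matrix,
        intronic_fraction=intronic,
        histone_scores=scores,
        s_phase_calls=s_calls,
        cluster_labels=labels,
        transfer=transfer,
        disn_table=disn_table,
        snm_table=snm_table,
        truth=truth,
    )
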