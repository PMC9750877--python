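"""Quality control: barnyard species calls, per-timepoint cell filtering and
count-matrix downsampling for gene-detection saturation curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "CellFilterSpec",
    "call_species",
    "filter_cells",
    "downsample_counts",
    "genes_detected",
]

#: per-timepoint log10 read floors used for the embryo series
DEFAULT_READ_FLOORS = {"E6.5": 4.0, "E7.5": 3.5, "E8.5": 3.5, "E9.5": 3.0}


def call_species(
    totals: pd.DataFrame,
    min_ufis: int = 7500,
    purity: float = 0.75,
    species_names: tuple[str, str] = ("species_a", "species_b"),
) -> pd.DataFrame:
    """Classify barnyard barcodes as singlets, doublets, or discarded.

    ``totals`` carries one row per barcode with per-species UFI (or gene)
    totals in columns ``species_names``.  Barcodes with a combined total below
    ``min_ufis`` are discarded; otherwise a barcode whose majority species
    holds a share strictly above ``purity`` is a singlet of that species, and
    anything else is a doublet (equivalently: more than 1 - purity of the
    UFIs belong to the other species).
    """
    a = totals[species_names[0]].to_numpy(dtype=float)
    b = totals[species_names[1]].to_numpy(dtype=float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        share_a = np.where(total > 0, a / total, 0.0)
    call = np.full(len(totals), "doublet", dtype=object)
    call[share_a > purity] = species_names[0]
    call[(1.0 - share_a) > purity] = species_names[1]
    call[total < min_ufis] = "discarded"
    out = totals.copy()
    out["total"] = total.astype(np.int64)
    out["call"] = call
    return out


@dataclass(frozen=True)
class CellFilterSpec:
    """Cell-retention rules: a per-timepoint log10 read floor, a transcript
    ceiling, and per-biotype transcript-fraction windows."""

    min_log10_reads: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_READ_FLOORS)
    )
    max_transcripts: float = 1e6
    protein_coding_window: tuple[float, float] = (0.85, 0.95)
    lncrna_window: tuple[float, float] = (0.01, 0.03)
    small_rna_window: tuple[float, float] = (0.05, 0.15)

    def __post_init__(self) -> None:
        for name in ("protein_coding_window", "lncrna_window", "small_rna_window"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lower < upper <= 1")


def filter_cells(
    adata: ad.AnnData,
    spec: CellFilterSpec,
    timepoint: str,
    fractions: pd.DataFrame | None = None,
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the per-timepoint cell filters.

    Requires ``adata.obs['n_reads']`` (raw reads per cell) and either a
    ``fractions`` frame with columns protein_coding/lncRNA/small_rna or
    biotype metadata in ``adata.var['biotype']`` to derive the per-cell
    transcript fractions.  Returns (retained cell index, per-criterion
    removal report).
    """
    if timepoint not in spec.min_log10_reads:
        raise ValueError(
            f"unknown timepoint {timepoint!r}; known: {sorted(spec.min_log10_reads)}"
        )
    if "n_reads" not in adata.obs:
        raise ValueError("adata.obs['n_reads'] is required for the read floor")
    reads = adata.obs["n_reads"].to_numpy(dtype=float)
    transcripts = np.asarray(adata.X.sum(axis=1), dtype=float).ravel()

    if fractions is None:
        from .feature_counting import SMALL_RNA_BIOTYPES

        biotype = adata.var["biotype"]
        groups = {
            "protein_coding": (biotype == "protein_coding").to_numpy(),
            "lncRNA": (biotype == "lncRNA").to_numpy(),
            "small_rna": biotype.isin(SMALL_RNA_BIOTYPES).to_numpy(),
        }
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions = pd.DataFrame(
                {
                    name: np.asarray(adata.X[:, mask].sum(axis=1)).ravel() / transcripts
                    for name, mask in groups.items()
                },
                index=adata.obs_names,
            ).fillna(0.0)

    checks = {
        "read_floor": reads > 10 ** spec.min_log10_reads[timepoint],
        "transcript_ceiling": transcripts < spec.max_transcripts,
        "protein_coding_window": fractions["protein_coding"].between(
            *spec.protein_coding_window
        ).to_numpy(),
        "lncrna_window": fractions["lncRNA"].between(*spec.lncrna_window).to_numpy(),
        "small_rna_window": fractions["small_rna"].between(*spec.small_rna_window).to_numpy(),
    }
    keep = np.ones(adata.n_obs, dtype=bool)
    report_rows = []
    for name, passed in checks.items():
        report_rows.append({"criterion": name, "removed": int((~passed).sum())})
        keep &= passed
    report = pd.DataFrame(report_rows)
    report.loc[len(report)] = {"criterion": "retained", "removed": int(keep.sum())}
    return adata.obs_names[keep], report


def downsample_counts(
    adata: ad.AnnData,
    input_reads: pd.Series | np.ndarray,
    target_reads: float | pd.Series | np.ndarray,
    seed: int = 0,
) -> ad.AnnData:
    """Binomially thin each cell's counts to a target sequencing depth.

    Every count entry of cell i is thinned independently with probability
    target_i / input_i, mimicking resequencing the cell at lower depth.
    Layers present on the input are thinned with the same per-cell
    probability (independently per layer; X is recomputed as their sum when
    both layers exist, otherwise thinned directly).
    """
    input_reads = np.asarray(input_reads, dtype=float)
    target = np.broadcast_to(np.asarray(target_reads, dtype=float), input_reads.shape)
    if np.any(target > input_reads):
        raise ValueError("target reads exceed input reads for at least one cell")
    p = np.divide(target, input_reads, out=np.zeros_like(target), where=input_reads > 0)
    rng = np.random.default_rng(seed)
    out = adata.copy()
    if "spliced" in adata.layers and "unspliced" in adata.layers:
        for layer in ("spliced", "unspliced"):
            counts = np.asarray(adata.layers[layer], dtype=np.int64)
            out.layers[layer] = rng.binomial(counts, p[:, None])
        out.X = out.layers["spliced"] + out.layers["unspliced"]
    else:
        counts = np.asarray(adata.X, dtype=np.int64)
        out.X = rng.binomial(counts, p[:, None])
    return out


def genes_detected(adata: ad.AnnData) -> pd.Series:
    """Per-cell number of uniquely assigned features with at least one molecule.

    Composite (multi-gene) features are excluded from the tally.
    """
    if "composite" in adata.var:
        mask = (~adata.var["composite"]).to_numpy()
    else:
        mask = np.ones(adata.n_vars, dtype=bool)
    X = np.asarray(adata.X)[:, mask]
    return pd.Series((X > 0).sum(axis=1), index=adata.obs_names, name="genes_detected")
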