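"""Cell identification from the barcode read-count distribution and
Hamming-distance barcode error correction.

Droplet barcodes split into two populations: barcodes that captured a cell
(high read counts) and ambient barcodes that only saw free-floating RNA
(low counts).  On a histogram of log10(reads per barcode) these form two
modes; the knee threshold is located as the local minimum of a polynomial
fit to the histogram, taking the minimum at the *largest* log10-read
position when the fit shows several.

Sequencing errors in barcodes are corrected by merging an observed barcode
into the whitelist entry within a maximum Hamming distance (2 for droplet
barcodes of 16 nt, 1 for the 384 plate barcodes of 8 nt) — but only when
that assignment is unique; ambiguous barcodes are left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UnimodalHistogramError",
    "BarcodeHistogram",
    "Whitelist",
    "knee_threshold",
    "accept_barcodes",
    "merge_barcodes",
    "dedupe_reads",
]

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class UnimodalHistogramError(ValueError):
    """The fitted histogram shows no interior local minimum, so no knee exists."""


@dataclass
class BarcodeHistogram:
    """Per-barcode raw read counts plus the binned log10 histogram."""

    counts: pd.Series  # index: barcode, values: raw read count (>= 1)
    n_bins: int = 100
    bin_edges: np.ndarray = field(init=False)
    bin_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts < 1).any():
            raise ValueError("observed barcodes must have at least one read")
        log10 = np.log10(counts.to_numpy(dtype=float))
        self.bin_counts, self.bin_edges = np.histogram(log10, bins=self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def knee_threshold(
    hist: BarcodeHistogram,
    poly_degree: int = 10,
    grid_points: int = 1000,
) -> float:
    """Locate the knee between ambient and cell barcodes.

    Fits a least-squares polynomial of ``poly_degree`` to the binned log10
    histogram and scans a dense grid of the fitted curve for local minima.
    Only *valley* minima count — minima lying between two interior local
    maxima of the curve (i.e. separating two modes); dips in the boundary
    tails of a high-degree fit are not knees.  Of the valleys, the one at the
    largest log10-read position is the threshold.  Raises
    :class:`UnimodalHistogramError` when the curve has no valley (callers may
    fall back to a fixed threshold).
    """
    x = hist.bin_centers
    y = hist.bin_counts.astype(float)
    if len(np.unique(np.log10(hist.counts.to_numpy(dtype=float)))) < 2:
        raise UnimodalHistogramError("all barcodes have identical read counts")
    poly = np.polynomial.Polynomial.fit(x, y, deg=poly_degree)
    grid = np.linspace(x[0], x[-1], grid_points)
    fitted = poly(grid)
    interior = np.arange(1, grid_points - 1)
    is_min = (fitted[interior] < fitted[interior - 1]) & (
        fitted[interior] <= fitted[interior + 1]
    )
    is_max = (fitted[interior] > fitted[interior - 1]) & (
        fitted[interior] >= fitted[interior + 1]
    )
    minima = grid[interior[is_min]]
    maxima = grid[interior[is_max]]
    if minima.size == 0 or maxima.size < 2:
        raise UnimodalHistogramError("fitted histogram has no valley between two modes")
    valleys = minima[(minima > maxima.min()) & (minima < maxima.max())]
    if valleys.size == 0:
        raise UnimodalHistogramError("fitted histogram has no valley between two modes")
    return float(valleys.max())


def accept_barcodes(counts: pd.Series, threshold_log10: float) -> pd.Index:
    """Barcodes with log10(reads) strictly above the knee threshold."""
    log10 = np.log10(counts.to_numpy(dtype=float))
    return counts.index[log10 > threshold_log10]


def _encode(barcodes, length: int) -> np.ndarray:
    arr = np.empty((len(barcodes), length), dtype=np.uint8)
    for i, bc in enumerate(barcodes):
        if len(bc) != length:
            raise ValueError(f"barcode {bc!r} does not have length {length}")
        arr[i] = [_BASES[b] for b in bc]
    return arr


@dataclass
class Whitelist:
    """Accepted barcodes plus the maximum merge distance (1 plate, 2 droplet)."""

    barcodes: tuple[str, ...]
    max_distance: int = 2

    def __post_init__(self) -> None:
        if self.max_distance not in (1, 2):
            raise ValueError("merge distance must be 1 (plate) or 2 (droplet)")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError("whitelist barcodes must share one length")
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        self._length = lengths.pop()
        self._encoded = _encode(self.barcodes, self._length)

    @property
    def length(self) -> int:
        return self._length


def merge_barcodes(observed: str, whitelist: Whitelist) -> str | None:
    """Uniquely assign an observed barcode to a whitelist entry.

    Returns the single whitelist barcode within ``max_distance`` Hamming
    distance of the observation, or None when zero or several candidates lie
    within the radius (the assignment must be unique to be trusted).
    """
    if len(observed) != whitelist.length:
        raise ValueError(
            f"observed barcode length {len(observed)} != whitelist length {whitelist.length}"
        )
    query = np.array([_BASES[b] for b in observed], dtype=np.uint8)
    dists = (whitelist._encoded != query).sum(axis=1)
    within = np.flatnonzero(dists <= whitelist.max_distance)
    if within.size != 1:
        return None
    return whitelist.barcodes[int(within[0])]


def merge_barcode_table(counts: pd.Series, whitelist: Whitelist) -> pd.Series:
    """Merge a per-barcode count table into whitelist barcodes.

    Counts of observed barcodes mapping to the same accepted barcode are
    summed; ambiguous/unmatched observations are dropped.
    """
    merged: dict[str, int] = {}
    for bc, n in counts.items():
        target = merge_barcodes(bc, whitelist)
        if target is not None:
            merged[target] = merged.get(target, 0) + int(n)
    return pd.Series(merged, dtype=np.int64).sort_index()


def dedupe_reads(reads: pd.DataFrame, feature_col: str = "feature") -> pd.DataFrame:
    """Collapse PCR duplicates: within a cell, reads sharing the same UFI and
    the same gene assignment are one molecule; the first occurrence survives.

    Reads with equal UFIs but different gene assignments are distinct
    molecules and all survive.
    """
    return reads.drop_duplicates(["barcode", "ufi", feature_col]).reset_index(drop=True)
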