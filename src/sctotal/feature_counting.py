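"""Read-to-feature assignment with spliced/unspliced status and UFI-aware counting.

Single-cell total RNA-seq reads cover whole gene bodies, so a read can land in
exons, introns, exon-intron junctions, or small non-coding RNAs nested inside
the introns of host genes.  Assignment follows a fixed hierarchy:

1. reads touching TEC (to-be-experimentally-confirmed) transcripts are discarded;
2. reads *fully* inside an intron-free small-RNA annotation (miscRNA, snoRNA,
   snRNA, miRNA, rRNA, ...) are assigned to it, with no spliced/unspliced status;
3. when several genes overlap the read, exonic hits take precedence over
   intronic ones; if the tie survives, the read is assigned to a composite
   feature named by all tied genes;
4. reads inside introns or crossing an exon-intron junction are unspliced,
   reads exclusively inside exons are spliced;
5. within one (cell, gene, UFI) group, a single unspliced read makes every
   read of that molecule unspliced (the fragment came from nascent RNA).

Counting collapses reads to molecules by (cell, feature, UFI, status) identity,
producing a cell x feature matrix with separate ``spliced``/``unspliced`` layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "AlignedRead",
    "Gene",
    "GeneAnnotation",
    "Assignment",
    "SMALL_RNA_BIOTYPES",
    "DISCARDED",
    "UNASSIGNED",
    "RRNA_REMOVED",
    "assign_read",
    "assign_reads",
    "deplete_rrna",
    "propagate_unspliced",
    "count_molecules",
    "restrict_terminal",
    "intronic_fraction",
]

#: biotypes without annotated introns; rule 2 of the hierarchy applies to these
SMALL_RNA_BIOTYPES = frozenset(
    {
        "miscRNA",
        "mtRNA",
        "mttRNA",
        "TrJGene",
        "miRNA",
        "rRNA",
        "ribozyme",
        "sRNA",
        "scaRNA",
        "snRNA",
        "snoRNA",
    }
)

DISCARDED = "__discarded__"
UNASSIGNED = "__unassigned__"
RRNA_REMOVED = "__rrna__"

SPLICED = "spliced"
UNSPLICED = "unspliced"
NOT_APPLICABLE = "not_applicable"

COMPOSITE_SEP = "–"  # en dash, joins gene names of composite features


@dataclass(frozen=True)
class AlignedRead:
    """One aligned sequenced fragment.

    ``blocks`` are 0-based half-open genomic intervals, sorted and
    non-overlapping (a spliced alignment has one block per exon it touches).
    """

    barcode: str
    ufi: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read must have at least one block")
        prev_end = -1
        for start, end in self.blocks:
            if not (start < end):
                raise ValueError(f"empty block [{start}, {end})")
            if start < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = end

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class Gene:
    """A gene with its exon structure; introns are the gaps between exons."""

    gene_id: str
    name: str
    biotype: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    histone: bool = False  # replication-dependent, non-polyadenylated histone
    non_polya: bool = False

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons))
        prev_end = -1
        for start, end in exons:
            if not (start < end):
                raise ValueError(f"empty exon [{start}, {end}) in {self.gene_id}")
            if start < prev_end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
            prev_end = end
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


class GeneAnnotation:
    """Gene models grouped per (chromosome, strand) for overlap queries.

    The container is deliberately small-scale: annotations here are toy genomes
    of a few hundred genes, so overlap queries scan the per-chromosome gene
    list filtered by a sorted-interval prefilter.
    """

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self._by_chrom: dict[tuple[str, str], list[Gene]] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
        # deterministic order: by chrom, start, gene id
        for gene in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            self._by_chrom.setdefault((gene.chrom, gene.strand), []).append(gene)
        self._starts = {
            key: np.array([g.start for g in gs]) for key, gs in self._by_chrom.items()
        }
        self._cummax_end = {
            key: np.maximum.accumulate([g.end for g in gs])
            for key, gs in self._by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, chrom: str, strand: str | None, start: int, end: int) -> list[Gene]:
        """Genes whose span overlaps [start, end); strand=None ignores strand."""
        keys = (
            [(chrom, strand)]
            if strand is not None
            else [(chrom, "+"), (chrom, "-")]
        )
        hits: list[Gene] = []
        for key in keys:
            genes = self._by_chrom.get(key)
            if not genes:
                continue
            hi = int(np.searchsorted(self._starts[key], end, side="left"))
            for i in range(hi):
                if self._cummax_end[key][i] <= start:
                    continue
                g = genes[i]
                if g.start < end and g.end > start:
                    hits.append(g)
        return sorted(hits, key=lambda g: g.gene_id)

    def rrna_intervals(self) -> list[tuple[str, int, int]]:
        return [
            (g.chrom, g.start, g.end)
            for g in self.genes.values()
            if g.biotype == "rRNA"
        ]

    def feature_frame(self) -> pd.DataFrame:
        """Per-feature metadata table (one spliced + one unspliced entry for
        intron-bearing biotypes is created later, at counting time)."""
        rows = [
            {
                "gene_id": g.gene_id,
                "name": g.name,
                "biotype": g.biotype,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "histone": g.histone,
                "non_polya": g.non_polya,
            }
            for g in sorted(self.genes.values(), key=lambda g: g.gene_id)
        ]
        return pd.DataFrame(rows).set_index("gene_id")

    def to_gtf(self, path: str) -> None:
        """Write the annotation as a minimal GTF (gene + exon records)."""
        with open(path, "w") as fh:
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
                attrs = (
                    f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tsctotal\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\tsctotal\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )


def read_gtf(path: str) -> GeneAnnotation:
    """Read a GTF written by :meth:`GeneAnnotation.to_gtf` (or any GTF using the
    gene_id/gene_name/gene_biotype attribute keys and exon features)."""
    import re

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    pat = re.compile(r'(\w+) "([^"]*)"')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            attrs = dict(pat.findall(fields[8]))
            gid = attrs["gene_id"]
            exons.setdefault(gid, []).append((int(fields[3]) - 1, int(fields[4])))
            meta[gid] = {
                "name": attrs.get("gene_name", gid),
                "biotype": attrs.get("gene_biotype", "protein_coding"),
                "chrom": fields[0],
                "strand": fields[6],
            }
    genes = [
        Gene(gene_id=gid, exons=tuple(sorted(set(ex))), **meta[gid])
        for gid, ex in exons.items()
    ]
    return GeneAnnotation(genes)


@dataclass(frozen=True)
class Assignment:
    """Outcome of the hierarchy for one read: exactly one feature (possibly a
    composite or a sentinel) and a splicing status."""

    feature: str
    status: str
    biotype: str | None = None

    @property
    def assigned(self) -> bool:
        return self.feature not in (DISCARDED, UNASSIGNED, RRNA_REMOVED)


def _blocks_within(blocks: Sequence[tuple[int, int]], interval: tuple[int, int]) -> bool:
    lo, hi = interval
    return all(lo <= s and e <= hi for s, e in blocks)


def _blocks_within_union(
    blocks: Sequence[tuple[int, int]], intervals: Sequence[tuple[int, int]]
) -> bool:
    """True when every block lies fully inside some single interval of the set."""
    for bs, be in blocks:
        if not any(s <= bs and be <= e for s, e in intervals):
            return False
    return True


def _overlaps_any(
    blocks: Sequence[tuple[int, int]], intervals: Iterable[tuple[int, int]]
) -> bool:
    return any(bs < e and be > s for bs, be in blocks for s, e in intervals)


def assign_read(
    read: AlignedRead, annotation: GeneAnnotation, strand_mode: str = "same"
) -> Assignment:
    """Apply the assignment hierarchy to one read.

    ``strand_mode='same'`` matches reads only to genes on the read's strand
    (the chemistry preserves strand); ``'ignore'`` considers both strands.
    """
    strand = read.strand if strand_mode == "same" else None
    candidates = annotation.overlapping(read.chrom, strand, read.start, read.end)
    candidates = [g for g in candidates if _overlaps_any(read.blocks, [(g.start, g.end)])]
    if not candidates:
        return Assignment(UNASSIGNED, NOT_APPLICABLE)

    # rule 1: any contact with a TEC transcript discards the read
    if any(g.biotype == "TEC" for g in candidates):
        return Assignment(DISCARDED, NOT_APPLICABLE)

    # rule 2: fully inside an intron-free small-RNA annotation
    small_hits = [
        g
        for g in candidates
        if g.biotype in SMALL_RNA_BIOTYPES and _blocks_within(read.blocks, (g.start, g.end))
    ]
    if small_hits:
        if len(small_hits) == 1:
            g = small_hits[0]
            return Assignment(g.gene_id, NOT_APPLICABLE, g.biotype)
        name = COMPOSITE_SEP.join(sorted(g.name for g in small_hits))
        return Assignment(name, NOT_APPLICABLE, "composite")

    genic = [g for g in candidates if g.biotype not in SMALL_RNA_BIOTYPES]
    if not genic:
        # partial overlap with a small RNA only: no intron-bearing gene to fall
        # back to, and "fully falling inside" failed
        return Assignment(UNASSIGNED, NOT_APPLICABLE)

    # rules 3-4: exonic hits take precedence over intronic ones
    exonic = [g for g in genic if _blocks_within_union(read.blocks, g.exons)]
    hits, status = (exonic, SPLICED) if exonic else (genic, UNSPLICED)
    if len(hits) == 1:
        g = hits[0]
        return Assignment(g.gene_id, status, g.biotype)
    name = COMPOSITE_SEP.join(sorted(g.name for g in hits))
    return Assignment(name, status, "composite")


def assign_reads(
    reads: pd.DataFrame, annotation: GeneAnnotation, strand_mode: str = "same"
) -> pd.DataFrame:
    """Assign a table of reads (columns: barcode, ufi, chrom, strand, blocks).

    ``blocks`` holds tuples of (start, end) pairs.  Returns the table with
    ``feature``, ``status`` and ``biotype`` columns appended.
    """
    features, statuses, biotypes = [], [], []
    for row in reads.itertuples(index=False):
        a = assign_read(
            AlignedRead(row.barcode, row.ufi, row.chrom, row.strand, tuple(row.blocks)),
            annotation,
            strand_mode=strand_mode,
        )
        features.append(a.feature)
        statuses.append(a.status)
        biotypes.append(a.biotype)
    out = reads.copy()
    out["feature"] = features
    out["status"] = statuses
    out["biotype"] = biotypes
    return out


def deplete_rrna(
    reads: pd.DataFrame, rrna_intervals: Sequence[tuple[str, int, int]]
) -> tuple[pd.DataFrame, dict]:
    """In-silico ribosomal depletion.

    Any read with at least one block overlapping an rRNA interval is removed,
    mirroring the pre-mapping rRNA filter.  Returns surviving reads and a
    depletion report ``{"input": n, "removed": r, "retained": n - r}``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in rrna_intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    keep = np.ones(len(reads), dtype=bool)
    for i, row in enumerate(reads.itertuples(index=False)):
        ivals = by_chrom.get(row.chrom)
        if ivals and _overlaps_any(row.blocks, ivals):
            keep[i] = False
    survivors = reads.loc[keep].reset_index(drop=True)
    report = {
        "input": int(len(reads)),
        "removed": int((~keep).sum()),
        "retained": int(keep.sum()),
    }
    return survivors, report


def propagate_unspliced(assignments: pd.DataFrame) -> pd.DataFrame:
    """UFI propagation: if any read of a (cell, feature, UFI) molecule is
    unspliced, every read of that molecule becomes unspliced.

    Small-RNA assignments (status ``not_applicable``) and unassigned reads are
    untouched.
    """
    out = assignments.copy()
    applicable = out["status"].isin([SPLICED, UNSPLICED])
    sub = out.loc[applicable]
    any_unspliced = (
        (sub["status"] == UNSPLICED)
        .groupby([sub["barcode"], sub["feature"], sub["ufi"]], observed=True)
        .transform("any")
    )
    out.loc[applicable, "status"] = np.where(any_unspliced, UNSPLICED, SPLICED)
    return out


def count_molecules(
    assignments: pd.DataFrame,
    annotation: GeneAnnotation,
    cells: Sequence[str] | None = None,
) -> ad.AnnData:
    """Collapse reads to molecules and build the count matrix.

    One molecule per distinct (cell, feature, UFI, status) after UFI
    propagation.  Returns an AnnData with ``spliced`` and ``unspliced`` layers
    (``X`` is their sum; small-RNA molecules count into the spliced layer for
    totals but carry biotype metadata identifying them), feature metadata
    (biotype, composite flag, histone flag) and per-cell biotype totals.
    """
    assigned = assignments[
        ~assignments["feature"].isin([DISCARDED, UNASSIGNED, RRNA_REMOVED])
    ]
    molecules = assigned.drop_duplicates(["barcode", "feature", "ufi", "status"])

    feat_meta = annotation.feature_frame()
    base_features = list(feat_meta.index)
    extra = sorted(set(molecules["feature"]) - set(base_features))
    features = base_features + extra
    fidx = {f: i for i, f in enumerate(features)}

    if cells is None:
        cells = sorted(assignments["barcode"].unique())
    cidx = {c: i for i, c in enumerate(cells)}

    spliced = np.zeros((len(cells), len(features)), dtype=np.int64)
    unspliced = np.zeros_like(spliced)
    for row in molecules.itertuples(index=False):
        ci = cidx.get(row.barcode)
        if ci is None:
            continue
        fi = fidx[row.feature]
        if row.status == UNSPLICED:
            unspliced[ci, fi] += 1
        else:  # spliced and not_applicable molecules
            spliced[ci, fi] += 1

    var = pd.DataFrame(index=pd.Index(features, name="feature"))
    var["biotype"] = [
        feat_meta.loc[f, "biotype"] if f in feat_meta.index else "composite"
        for f in features
    ]
    var["composite"] = [f not in feat_meta.index for f in features]
    var["histone"] = [
        bool(feat_meta.loc[f, "histone"]) if f in feat_meta.index else False
        for f in features
    ]

    adata = ad.AnnData(
        X=(spliced + unspliced).astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(list(cells), name="cell")),
        var=var,
        layers={"spliced": spliced, "unspliced": unspliced},
    )
    totals = adata.X.sum(axis=1)
    adata.obs["total_molecules"] = np.asarray(totals).ravel()
    for biotype in sorted(var["biotype"].unique()):
        mask = (var["biotype"] == biotype).to_numpy()
        adata.obs[f"n_{biotype}"] = np.asarray(adata.X[:, mask].sum(axis=1)).ravel()
    return adata


def _exonic_coordinate(gene: Gene, pos: float) -> float:
    """Project a genomic position onto cumulative exonic (spliced) coordinates.

    Positions inside an intron map to the exonic offset at the intron's start,
    so intron-touching reads inherit the position of the surrounding junction.
    """
    acc = 0.0
    for s, e in gene.exons:
        if pos < s:
            return acc
        if pos < e:
            return acc + (pos - s)
        acc += e - s
    return acc


def restrict_terminal(
    assignments: pd.DataFrame,
    annotation: GeneAnnotation,
    terminal_fraction: float = 0.2,
) -> pd.DataFrame:
    """Keep reads whose midpoint lies in the 3'-terminal window of the gene body.

    The window is measured along spliced (exon-projected) coordinates and is
    strand-aware: for a plus-strand gene of exonic length L and fraction f, the
    retained window is [(1-f)*L, L); for minus-strand genes it is [0, f*L).
    Reads on composite or sentinel features, and small-RNA reads, pass through
    unchanged (single-exon features are their own gene body).
    """
    if not (0 < terminal_fraction <= 1):
        raise ValueError("terminal_fraction must be in (0, 1]")
    if terminal_fraction == 1.0:
        return assignments.copy()
    keep = np.ones(len(assignments), dtype=bool)
    for i, row in enumerate(assignments.itertuples(index=False)):
        gene = annotation.genes.get(row.feature)
        if gene is None or row.status == NOT_APPLICABLE:
            continue
        mid = (row.blocks[0][0] + row.blocks[-1][1]) / 2.0
        x = _exonic_coordinate(gene, mid)
        L = gene.exonic_length
        if gene.strand == "+":
            keep[i] = x >= (1.0 - terminal_fraction) * L
        else:
            keep[i] = x < terminal_fraction * L
    return assignments.loc[keep].reset_index(drop=True)


def intronic_fraction(adata: ad.AnnData) -> pd.Series:
    """Per-cell fraction of unspliced molecules: u / (u + s).

    Computed over intron-bearing features only (small-RNA biotypes carry no
    spliced/unspliced status and are excluded).  Cells without any
    status-bearing molecule get NaN.
    """
    mask = (~adata.var["biotype"].isin(SMALL_RNA_BIOTYPES)).to_numpy()
    u = np.asarray(adata.layers["unspliced"][:, mask].sum(axis=1), dtype=float).ravel()
    s = np.asarray(adata.layers["spliced"][:, mask].sum(axis=1), dtype=float).ravel()
    total = u + s
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, u / total, np.nan)
    return pd.Series(frac, index=adata.obs_names, name="intronic_fraction")
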