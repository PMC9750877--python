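"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure of a droplet total-RNA
experiment rather than sequence-level realism:

* a bimodal log10(reads-per-barcode) distribution — a low ambient mode and a
  high cell mode separated by a valley (the knee);
* a toy two-species annotation with multi-exon protein-coding genes,
  single-exon non-polyadenylated histone genes, lncRNAs, intron-free small
  RNAs (one nested in a protein-coding intron), rRNA intervals, a TEC gene,
  one exonic-over-intronic and one exonic-over-exonic overlapping gene pair;
* reads with planted spliced/unspliced status, geometric PCR copy counts and
  per-nucleotide barcode substitution errors;
* bimodal histone content (S-phase cells draw from a high mode);
* heterotypic doublet barcodes mixing the two species;
* two "technologies" sampling the same planted clusters at different depth
  and biotype bias;
* splicing nodes with cluster-specific planted percent-spliced-in values.

Every function is deterministic given the config seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_counting import Gene, GeneAnnotation, SMALL_RNA_BIOTYPES

__all__ = [
    "SyntheticConfig",
    "ClusterSpec",
    "GroundTruth",
    "ConfigurationError",
    "make_annotation",
    "sample_barcode_read_totals",
    "simulate_reads",
    "simulate_species_mixture",
    "simulate_technologies",
    "simulate_splice_counts",
]

_ALPHABET = np.array(list("ACGT"))

REQUIRED_BIOTYPES = ("protein_coding", "histone", "snoRNA", "rRNA")


class ConfigurationError(ValueError):
    """The synthetic configuration violates an invariant."""


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster: id, cells per technology, marker-gene boost."""

    cluster_id: str
    size_per_tech: dict[str, int]
    marker_boost: float = 8.0


def _default_biotype_counts() -> dict[str, int]:
    return {
        "protein_coding": 12,
        "histone": 6,
        "lncRNA": 6,
        "snoRNA": 3,
        "snRNA": 2,
        "miscRNA": 2,
        "rRNA": 2,
        "TEC": 1,
    }


def _default_clusters() -> tuple[ClusterSpec, ...]:
    return tuple(
        ClusterSpec(f"C{i}", {"total": 150, "capture": 150}) for i in range(4)
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic experiment.

    Read-depth modes are given in log10 reads per barcode; with the defaults
    the valley between the ambient and the cell mode sits near log10 = 3.0.
    Histone means are expected histone molecules per cell in the two
    cell-cycle modes; the low/high separation makes a raw-count threshold of
    35 meaningful.
    """

    seed: int = 0
    n_real_cells: int = 500
    n_ambient_barcodes: int = 5000
    barcode_length: int = 16
    ufi_length: int = 6
    error_rate: float = 0.005  # substitutions per barcode nucleotide
    n_genes_per_biotype: dict[str, int] = field(default_factory=_default_biotype_counts)
    species_labels: tuple[str, str] = ("mouse", "human")
    doublet_fraction: float = 0.03
    s_phase_fraction: float = 0.65
    histone_high_mean: float = 80.0
    histone_low_mean: float = 8.0
    cell_log10_reads_mean: float = 3.6
    cell_log10_reads_sd: float = 0.15
    ambient_log10_reads_mean: float = 2.3
    ambient_log10_reads_sd: float = 0.25
    duplication_p: float = 0.5  # geometric PCR copy count, support {1, 2, ...}
    unspliced_fraction: float = 0.44
    rrna_fraction: float = 0.05
    cluster_spec: tuple[ClusterSpec, ...] = field(default_factory=_default_clusters)
    psi_spec: tuple[tuple[str, str, float], ...] = ()

    def validate(self) -> None:
        fractions = {
            "error_rate": self.error_rate,
            "doublet_fraction": self.doublet_fraction,
            "s_phase_fraction": self.s_phase_fraction,
            "unspliced_fraction": self.unspliced_fraction,
            "rrna_fraction": self.rrna_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_real_cells", "n_ambient_barcodes", "barcode_length", "ufi_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.species_labels[0] == self.species_labels[1]:
            raise ConfigurationError("the two species labels must be distinct")
        for biotype in REQUIRED_BIOTYPES:
            if self.n_genes_per_biotype.get(biotype, 0) <= 0:
                raise ConfigurationError(f"required biotype {biotype!r} has zero genes")
        if self.n_genes_per_biotype["protein_coding"] < 5:
            raise ConfigurationError(
                "need >= 5 protein-coding genes per species to host the nested "
                "small RNA and the two overlapping gene pairs"
            )
        for _, _, psi in self.psi_spec:
            if not (0.0 <= psi <= 1.0):
                raise ConfigurationError(f"planted psi {psi} outside [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for everything the generator emitted."""

    barcode_to_cell: dict[str, str]
    cell_species: dict[str, str]  # species label or "doublet"
    cell_s_phase: dict[str, bool]
    cell_cluster: dict[str, dict[str, str]]  # technology -> cell -> cluster
    read_truth: pd.DataFrame  # read_id, cell, true_barcode, gene, status
    molecules: pd.DataFrame  # cell, gene, ufi, status (one row per molecule)
    barcode_read_totals: pd.Series  # true barcode -> emitted read count
    n_rrna_reads: int
    node_psi: dict[tuple[str, str], float]  # (node, cluster) -> psi


# ---------------------------------------------------------------------------
# annotation


def _letters(i: int) -> str:
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = string.ascii_uppercase[r] + out
    return out


def make_annotation(config: SyntheticConfig) -> GeneAnnotation:
    """Build the deterministic toy two-species annotation.

    Layout guarantees (per species, on one chromosome):

    * the first protein-coding gene hosts a snoRNA strictly inside its first
      intron (same strand);
    * protein-coding genes 2 and 3 form an exonic-over-intronic pair (gene 3
      lies entirely inside an intron of gene 2);
    * protein-coding genes 4 and 5 share an exonic stretch (exonic-over-exonic
      overlap, yielding composite assignments);
    * histone genes are single-exon, flagged histone and non-polyadenylated;
    * small-RNA genes are intron-free intervals; rRNA genes provide the
      depletion reference; one TEC gene exercises the discard rule.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes: list[Gene] = []
    counts = config.n_genes_per_biotype

    for species in config.species_labels:
        chrom = f"{species}_chr1"
        cursor = 1000
        sp = species[:2]

        def pc_exons(n_exons: int, exon_len=200, intron_len=500, start=None):
            nonlocal cursor
            s = cursor if start is None else start
            exons = []
            pos = s
            for _ in range(n_exons):
                exons.append((pos, pos + exon_len))
                pos += exon_len + intron_len
            pos -= intron_len
            if start is None:
                cursor = pos + 800
            return tuple(exons)

        n_pc = counts["protein_coding"]
        strands = ["+", "-"] * (n_pc // 2 + 1)

        # pc gene 0: host with a nested snoRNA in intron 1
        host_exons = pc_exons(3, exon_len=250, intron_len=900)
        genes.append(
            Gene(f"{sp}PC{_letters(0)}", f"{sp}Pc{_letters(0).lower()}",
                 "protein_coding", chrom, strands[0], host_exons)
        )
        intron = (host_exons[0][1], host_exons[1][0])
        sno_start = intron[0] + 200
        genes.append(
            Gene(f"{sp}SNO0", f"{sp}Snord0", "snoRNA", chrom, strands[0],
                 ((sno_start, sno_start + 120),))
        )

        # pc genes 1 & 2: exonic-over-intronic pair (gene 2 inside gene 1 intron)
        outer_exons = pc_exons(3, exon_len=200, intron_len=2500)
        genes.append(
            Gene(f"{sp}PC{_letters(1)}", f"{sp}Pc{_letters(1).lower()}",
                 "protein_coding", chrom, strands[1], outer_exons)
        )
        inner_intron = (outer_exons[1][1], outer_exons[2][0])
        inner_start = inner_intron[0] + 300
        inner_exons = (
            (inner_start, inner_start + 250),
            (inner_start + 650, inner_start + 900),
        )
        genes.append(
            Gene(f"{sp}PC{_letters(2)}", f"{sp}Pc{_letters(2).lower()}",
                 "protein_coding", chrom, strands[1], inner_exons)
        )

        # pc genes 3 & 4: exonic-over-exonic overlap (shared exonic stretch)
        a_exons = pc_exons(3, exon_len=300, intron_len=400)
        genes.append(
            Gene(f"{sp}PC{_letters(3)}", f"{sp}Pc{_letters(3).lower()}",
                 "protein_coding", chrom, strands[2], a_exons)
        )
        last = a_exons[-1]
        b_first = (last[0] + 100, last[1] + 200)  # overlaps a's last exon
        b_exons = (b_first, (b_first[1] + 400, b_first[1] + 700))
        genes.append(
            Gene(f"{sp}PC{_letters(4)}", f"{sp}Pc{_letters(4).lower()}",
                 "protein_coding", chrom, strands[2], b_exons)
        )
        cursor = max(cursor, b_exons[-1][1] + 800)

        # remaining ordinary multi-exon protein-coding genes
        for i in range(5, n_pc):
            n_exons = int(rng.integers(3, 6))
            genes.append(
                Gene(f"{sp}PC{_letters(i)}", f"{sp}Pc{_letters(i).lower()}",
                     "protein_coding", chrom, strands[i % len(strands)],
                     pc_exons(n_exons))
            )

        # single-exon, non-polyadenylated histone genes
        for i in range(counts.get("histone", 0)):
            start = cursor
            cursor += 400 + 600
            genes.append(
                Gene(f"{sp}HIST{i}", f"{sp}H{i}", "protein_coding", chrom,
                     strands[i % 2], ((start, start + 400),),
                     histone=True, non_polya=True)
            )

        # two-exon lncRNAs
        for i in range(counts.get("lncRNA", 0)):
            genes.append(
                Gene(f"{sp}LNC{i}", f"{sp}Linc{i}", "lncRNA", chrom,
                     strands[i % 2], pc_exons(2, exon_len=300, intron_len=600))
            )

        # intergenic small RNAs (one snoRNA already nested above)
        for biotype, prefix in (("snoRNA", "SNO"), ("snRNA", "SNR"), ("miscRNA", "MISC")):
            n = counts.get(biotype, 0)
            start_idx = 1 if biotype == "snoRNA" else 0
            for i in range(start_idx, n):
                start = cursor
                cursor += 120 + 500
                genes.append(
                    Gene(f"{sp}{prefix}{i}", f"{sp}{prefix.capitalize()}{i}",
                         biotype, chrom, strands[i % 2], ((start, start + 120),))
                )

        for i in range(counts.get("rRNA", 0)):
            start = cursor
            cursor += 1500 + 800
            genes.append(
                Gene(f"{sp}RRNA{i}", f"{sp}Rn{i}", "rRNA", chrom, "+",
                     ((start, start + 1500),))
            )

        for i in range(counts.get("TEC", 0)):
            genes.append(
                Gene(f"{sp}TEC{i}", f"{sp}Tec{i}", "TEC", chrom,
                     strands[i % 2], pc_exons(2))
            )

    return GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# barcode-level totals (the knee's input)


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = _ALPHABET[rng.integers(0, 4, size=(n - len(out), length))]
        for row in block:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def sample_barcode_read_totals(
    config: SyntheticConfig,
) -> tuple[pd.Series, pd.Index]:
    """Per-barcode read totals under the bimodal depth model.

    Returns (totals over all barcodes, index of the true cell barcodes).
    This is the knee detector's input and is cheap at any scale because no
    individual reads are emitted.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    barcodes = _random_barcodes(
        rng, config.n_real_cells + config.n_ambient_barcodes, config.barcode_length
    )
    cell_bc = barcodes[: config.n_real_cells]
    ambient_bc = barcodes[config.n_real_cells:]
    cell_reads = np.round(
        10 ** rng.normal(config.cell_log10_reads_mean, config.cell_log10_reads_sd,
                         config.n_real_cells)
    ).astype(np.int64)
    ambient_reads = np.round(
        10 ** rng.normal(config.ambient_log10_reads_mean, config.ambient_log10_reads_sd,
                         config.n_ambient_barcodes)
    ).astype(np.int64)
    totals = pd.Series(
        np.concatenate([cell_reads, ambient_reads]).clip(min=1),
        index=pd.Index(cell_bc + ambient_bc, name="barcode"),
        name="reads",
    )
    return totals, pd.Index(cell_bc, name="barcode")


# ---------------------------------------------------------------------------
# reads


def _gene_position_pools(annotation: GeneAnnotation):
    """Per gene: sub-intervals where a read is unambiguously assignable back
    to that gene (used so planted truth matches the assignment hierarchy).

    Exonic pools subtract same-strand spans of other genes; intronic pools
    additionally subtract small-RNA intervals nested in introns.
    """

    def subtract(intervals, cuts):
        out = list(intervals)
        for cs, ce in cuts:
            nxt = []
            for s, e in out:
                if ce <= s or cs >= e:
                    nxt.append((s, e))
                    continue
                if s < cs:
                    nxt.append((s, cs))
                if ce < e:
                    nxt.append((ce, e))
            out = nxt
        return [(s, e) for s, e in out if e - s >= 60]

    pools = {}
    for gene in annotation.genes.values():
        others = [
            (g.start, g.end)
            for g in annotation.overlapping(gene.chrom, gene.strand, gene.start, gene.end)
            if g.gene_id != gene.gene_id
        ]
        exonic = subtract(gene.exons, others)
        intronic = subtract(gene.introns, others)
        pools[gene.gene_id] = (exonic, intronic, gene)
    return pools


def _ufi_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    block = _ALPHABET[rng.integers(0, 4, size=(n, length))]
    return ["".join(row) for row in block]


def _int_to_ufi(value: int, length: int) -> str:
    out = []
    for _ in range(length):
        value, r = divmod(value, 4)
        out.append("ACGT"[r])
    return "".join(out)


def _unique_ufis_per_gene(
    rng: np.random.Generator, gene_draws: list[str], length: int
) -> list[str]:
    """Distinct UFIs within each (cell, gene) group so that every planted
    molecule stays a distinct molecule after UMI-identity collapsing."""
    space = 4**length
    by_gene: dict[str, list[int]] = {}
    for i, g in enumerate(gene_draws):
        by_gene.setdefault(g, []).append(i)
    ufis = [""] * len(gene_draws)
    for g, idx in by_gene.items():
        if len(idx) > space:
            raise ConfigurationError(
                f"{len(idx)} molecules of {g} exceed the UFI space 4^{length}"
            )
        codes = rng.choice(space, size=len(idx), replace=False)
        for i, code in zip(idx, codes):
            ufis[i] = _int_to_ufi(int(code), length)
    return ufis


def simulate_reads(
    annotation: GeneAnnotation, config: SyntheticConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit the aligned-read stream with planted ground truth.

    Per real cell: molecule count follows the log-normal cell mode (reads =
    molecules x geometric PCR copies), genes are drawn from a species-specific
    expression profile, histone molecules come from the S-phase-dependent
    mode, a planted fraction of status-bearing molecules is unspliced, and a
    planted fraction of molecules is rRNA (to be removed by depletion).
    Ambient barcodes draw few reads from the ambient mode.  Barcode
    substitutions are applied per emitted read at ``error_rate`` per
    nucleotide.  Doublet barcodes mix both species' gene pools.
    """
    config.validate()
    totals, cell_index = sample_barcode_read_totals(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pools = _gene_position_pools(annotation)
    mean_dup = 1.0 / config.duplication_p

    species_genes: dict[str, dict[str, list[str]]] = {}
    for sp in config.species_labels:
        sp_genes = [g for g in annotation.genes.values() if g.chrom.startswith(sp)]
        species_genes[sp] = {
            "expressed": [
                g.gene_id
                for g in sp_genes
                if not g.histone
                and g.biotype not in ("TEC", "rRNA")
                and pools[g.gene_id][0]
            ],
            "histone": [g.gene_id for g in sp_genes if g.histone],
            "rrna": [g.gene_id for g in sp_genes if g.biotype == "rRNA"],
        }
    weights = {
        sp: rng.dirichlet(np.full(len(d["expressed"]), 2.0))
        for sp, d in species_genes.items()
    }

    n_cells = config.n_real_cells
    cells = [f"cell_{i:05d}" for i in range(n_cells)]
    barcode_to_cell = dict(zip(cell_index, cells))
    n_doublets = int(round(config.doublet_fraction * n_cells))
    doublet_ids = set(rng.choice(n_cells, size=n_doublets, replace=False).tolist())
    half = n_cells // 2
    cell_species = {}
    for i, cell in enumerate(cells):
        if i in doublet_ids:
            cell_species[cell] = "doublet"
        else:
            cell_species[cell] = config.species_labels[0] if i < half else config.species_labels[1]
    s_flags = rng.random(n_cells) < config.s_phase_fraction
    cell_s_phase = {cell: bool(s_flags[i]) for i, cell in enumerate(cells)}

    read_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    mol_rows: list[tuple] = []
    n_rrna_reads = 0
    read_counter = 0
    bc_totals: dict[str, int] = {}

    def emit(true_bc, cell, gene_id, ufi, status, copies, blocks_list):
        nonlocal read_counter, n_rrna_reads
        gene = annotation.genes[gene_id]
        for c in range(copies):
            rid = f"r{read_counter:08d}"
            read_counter += 1
            observed = true_bc
            n_err = rng.binomial(config.barcode_length, config.error_rate)
            if n_err:
                pos = rng.choice(config.barcode_length, size=n_err, replace=False)
                bc_arr = list(observed)
                for p in pos:
                    choices = [b for b in "ACGT" if b != bc_arr[p]]
                    bc_arr[p] = choices[int(rng.integers(0, 3))]
                observed = "".join(bc_arr)
            blocks = blocks_list[c if len(blocks_list) > 1 else 0]
            read_rows.append((rid, observed, ufi, gene.chrom, gene.strand, blocks))
            truth_rows.append((rid, cell, true_bc, gene_id, status))
            if gene.biotype == "rRNA":
                n_rrna_reads += 1
        bc_totals[true_bc] = bc_totals.get(true_bc, 0) + copies

    def sample_block(intervals, length=60):
        lens = np.array([e - s for s, e in intervals], dtype=float)
        i = int(rng.choice(len(intervals), p=lens / lens.sum()))
        s, e = intervals[i]
        start = int(rng.integers(s, max(s + 1, e - length)))
        return ((start, min(start + length, e)),)

    def molecule_blocks(gene, status, exonic, intronic):
        """Pick alignment blocks consistent with the planted status."""
        if status == "unspliced":
            if intronic and rng.random() < 0.5:
                return sample_block(intronic)
            # junction read straddling an exon-intron boundary
            k = int(rng.integers(0, len(gene.introns)))
            istart, iend = gene.introns[k]
            if rng.random() < 0.5:
                return ((istart - 30, istart + 30),)
            return ((iend - 30, iend + 30),)
        if status == "spliced" and len(gene.exons) > 1 and rng.random() < 0.2:
            # exon-exon junction read: two blocks, still exon-only
            k = int(rng.integers(0, len(gene.exons) - 1))
            (s1, e1), (s2, e2) = gene.exons[k], gene.exons[k + 1]
            return ((max(s1, e1 - 30), e1), (s2, min(e2, s2 + 30)))
        return sample_block(exonic if exonic else [gene.exons[0]])

    for i, (bc, cell) in enumerate(barcode_to_cell.items()):
        n_molecules = max(1, int(round(totals.loc[bc] / mean_dup)))
        sp = cell_species[cell]
        if sp == "doublet":
            f = rng.uniform(0.35, 0.65)
            n_a = rng.binomial(n_molecules, f)
            parts = [(config.species_labels[0], n_a),
                     (config.species_labels[1], n_molecules - n_a)]
        else:
            parts = [(sp, n_molecules)]

        for part_sp, n_part in parts:
            if n_part == 0:
                continue
            pool = species_genes[part_sp]
            n_rrna = rng.binomial(n_part, config.rrna_fraction)
            n_hist = min(
                n_part - n_rrna,
                rng.poisson(
                    config.histone_high_mean if cell_s_phase[cell] else config.histone_low_mean
                ),
            )
            n_expr = n_part - n_rrna - n_hist

            gene_draws: list[str] = []
            if n_expr > 0:
                idx = rng.choice(len(pool["expressed"]), size=n_expr, p=weights[part_sp])
                gene_draws += [pool["expressed"][j] for j in idx]
            if n_hist > 0:
                idx = rng.integers(0, len(pool["histone"]), size=n_hist)
                gene_draws += [pool["histone"][j] for j in idx]
            if n_rrna > 0:
                idx = rng.integers(0, len(pool["rrna"]), size=n_rrna)
                gene_draws += [pool["rrna"][j] for j in idx]

            # planted unspliced share among status-bearing molecules, rescaled
            # so single-exon (histone) molecules do not dilute it
            multi = np.array([len(annotation.genes[g].exons) > 1 for g in gene_draws])
            statusable = np.array(
                [annotation.genes[g].biotype not in SMALL_RNA_BIOTYPES for g in gene_draws]
            )
            n_multi = int((multi & statusable).sum())
            n_statusable = int(statusable.sum())
            p_u = 0.0
            if n_multi:
                p_u = min(1.0, config.unspliced_fraction * n_statusable / n_multi)

            ufis = _unique_ufis_per_gene(rng, gene_draws, config.ufi_length)
            copies = rng.geometric(config.duplication_p, size=len(gene_draws))
            unspliced_draw = rng.random(len(gene_draws)) < p_u

            for j, gene_id in enumerate(gene_draws):
                gene = annotation.genes[gene_id]
                exonic, intronic, _ = pools[gene_id]
                if gene.biotype in SMALL_RNA_BIOTYPES:
                    status = "not_applicable"
                elif multi[j] and unspliced_draw[j]:
                    status = "unspliced"
                else:
                    status = "spliced"
                n_copies = int(copies[j])
                blocks = molecule_blocks(gene, status, exonic, intronic)
                blocks_list = [blocks]
                if status == "unspliced" and n_copies > 1 and rng.random() < 0.3 and exonic:
                    # one PCR sibling aligns exon-only: exercises UFI propagation
                    blocks_list = [blocks] * n_copies
                    blocks_list[1] = sample_block(exonic)
                emit(bc, cell, gene_id, ufis[j], status, n_copies, blocks_list)
                if gene.biotype != "rRNA":
                    mol_rows.append((cell, gene_id, ufis[j], status))

    # ambient barcodes: few reads, drawn from both species' expressed pools
    ambient_bcs = [bc for bc in totals.index if bc not in barcode_to_cell]
    all_expressed = [
        (sp, j) for sp in config.species_labels
        for j in range(len(species_genes[sp]["expressed"]))
    ]
    for bc in ambient_bcs:
        n_molecules = max(1, int(round(totals.loc[bc] / mean_dup)))
        idx = rng.integers(0, len(all_expressed), size=n_molecules)
        ufis = _ufi_strings(rng, n_molecules, config.ufi_length)
        copies = rng.geometric(config.duplication_p, size=n_molecules)
        for j in range(n_molecules):
            sp, gi = all_expressed[int(idx[j])]
            gene_id = species_genes[sp]["expressed"][gi]
            gene = annotation.genes[gene_id]
            exonic, intronic, _ = pools[gene_id]
            status = (
                "not_applicable" if gene.biotype in SMALL_RNA_BIOTYPES else "spliced"
            )
            blocks = molecule_blocks(gene, status, exonic, intronic)
            emit(bc, f"ambient:{bc}", gene_id, ufis[j], status, int(copies[j]), [blocks])

    reads = pd.DataFrame(
        read_rows, columns=["read_id", "barcode", "ufi", "chrom", "strand", "blocks"]
    )
    # shuffle the stream deterministically so cell reads are interleaved
    order = rng.permutation(len(reads))
    reads = reads.iloc[order].reset_index(drop=True)

    cluster_map = _cluster_assignment(config, cells)
    truth = GroundTruth(
        barcode_to_cell=barcode_to_cell,
        cell_species=cell_species,
        cell_s_phase=cell_s_phase,
        cell_cluster=cluster_map,
        read_truth=pd.DataFrame(
            truth_rows, columns=["read_id", "cell", "true_barcode", "gene", "status"]
        ),
        molecules=pd.DataFrame(mol_rows, columns=["cell", "gene", "ufi", "status"]),
        barcode_read_totals=pd.Series(bc_totals, name="reads"),
        n_rrna_reads=n_rrna_reads,
        node_psi={},
    )
    return reads, truth


def _cluster_assignment(config: SyntheticConfig, cells: list[str]) -> dict[str, dict[str, str]]:
    if not config.cluster_spec:
        return {}
    ids = [c.cluster_id for c in config.cluster_spec]
    return {
        "total": {cell: ids[i % len(ids)] for i, cell in enumerate(cells)}
    }


# ---------------------------------------------------------------------------
# species-mixing totals (barnyard experiment at QC scale)


def simulate_species_mixture(
    n_barcodes: int = 2000,
    doublet_fraction: float = 0.03,
    mean_ufis: float = 20000.0,
    low_quality_fraction: float = 0.05,
    contamination: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-barcode species UFI totals for the barnyard doublet test.

    Singlets carry a small cross-species contamination; doublets mix the two
    species with a fraction uniform on (0.35, 0.65) (two comparable cells);
    a ``low_quality_fraction`` of barcodes falls under the UFI floor.
    Returns a frame with columns species_a, species_b, truth.
    """
    rng = np.random.default_rng(seed)
    truth = np.where(rng.random(n_barcodes) < doublet_fraction, "doublet", "singlet")
    species = rng.integers(0, 2, size=n_barcodes)
    totals = rng.poisson(mean_ufis, size=n_barcodes).astype(float)
    low = rng.random(n_barcodes) < low_quality_fraction
    totals[low] = rng.uniform(500, 7000, size=int(low.sum()))
    frac_a = np.where(species == 0, 1.0 - contamination, contamination).astype(float)
    is_doublet = truth == "doublet"
    frac_a[is_doublet] = rng.uniform(0.35, 0.65, size=int(is_doublet.sum()))
    a = rng.binomial(totals.astype(np.int64), frac_a)
    rows = pd.DataFrame(
        {
            "species_a": a,
            "species_b": totals.astype(np.int64) - a,
            "truth": np.where(low, "low_quality", truth),
        },
        index=pd.Index([f"bc{i:05d}" for i in range(n_barcodes)], name="barcode"),
    )
    return rows


# ---------------------------------------------------------------------------
# two technologies over shared clusters


def simulate_technologies(
    config: SyntheticConfig,
    n_genes: int = 300,
    depth: dict[str, float] | None = None,
    noise_sd: float = 0.25,
):
    """Count matrices for two technologies sampling the same planted clusters.

    Each cluster gets a log-normal expression profile with a dedicated block
    of boosted marker genes shared across technologies; technologies differ in
    depth and in a biotype-like bias (the second technology downweights the
    last third of genes, standing in for 3'-capture losing non-coding RNA).
    Returns (dict tech -> AnnData with obs['cluster'], ground-truth dict).
    """
    import anndata as ad

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    depth = depth or {"total": 2000.0, "capture": 1000.0}
    clusters = config.cluster_spec
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    n_markers = max(3, n_genes // (len(clusters) * 6))
    profiles = {}
    for i, spec in enumerate(clusters):
        prof = base.copy()
        lo = i * n_markers
        prof[lo: lo + n_markers] *= spec.marker_boost
        profiles[spec.cluster_id] = prof / prof.sum()

    tech_bias = {}
    for t, tech in enumerate(depth):
        bias = np.ones(n_genes)
        if t == 1:
            bias[2 * n_genes // 3:] = 1.0 / 3.0
        tech_bias[tech] = bias

    out = {}
    truth_clusters: dict[str, dict[str, str]] = {}
    for tech in depth:
        rows, labels, names = [], [], []
        for spec in clusters:
            n = spec.size_per_tech.get(tech, 0)
            lam = profiles[spec.cluster_id] * tech_bias[tech]
            lam = lam / lam.sum() * depth[tech]
            # per-cell log-normal depth wobble
            scale = rng.lognormal(0.0, noise_sd, size=n)
            counts = rng.poisson(lam[None, :] * scale[:, None])
            rows.append(counts)
            labels += [spec.cluster_id] * n
            names += [f"{tech}_{spec.cluster_id}_{j:04d}" for j in range(n)]
        X = np.vstack(rows).astype(np.int64)
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame({"cluster": labels}, index=pd.Index(names, name="cell")),
            var=pd.DataFrame(index=pd.Index([f"g{j:04d}" for j in range(n_genes)], name="gene")),
        )
        out[tech] = adata
        truth_clusters[tech] = dict(zip(names, labels))
    return out, truth_clusters


# ---------------------------------------------------------------------------
# splicing-node counts


def simulate_splice_counts(
    psi_spec: dict[tuple[str, str], float] | list[tuple[str, str, float]],
    cells_per_cluster: dict[str, int],
    reads_per_node: float = 20.0,
    seed: int = 0,
    annotation: GeneAnnotation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Node x cell inclusion/exclusion counts with planted per-cluster psi.

    For each cell of cluster c and node n: total reads ~ Poisson(reads_per_node),
    inclusion ~ Binomial(total, psi[n, c]), exclusion = total - inclusion.
    Returns (inclusion frame, exclusion frame, ground truth); frames are
    cells x nodes with a ``cluster`` column stored in the truth.
    """
    if isinstance(psi_spec, list):
        psi_spec = {(node, cluster): psi for node, cluster, psi in psi_spec}
    for (node, cluster), psi in psi_spec.items():
        if not (0.0 <= psi <= 1.0):
            raise ConfigurationError(f"planted psi {psi} for {node}/{cluster} outside [0, 1]")
    nodes = sorted({node for node, _ in psi_spec})
    rng = np.random.default_rng(seed)
    cell_names, cell_clusters = [], []
    for cluster in sorted(cells_per_cluster):
        for j in range(cells_per_cluster[cluster]):
            cell_names.append(f"{cluster}_cell{j:04d}")
            cell_clusters.append(cluster)
    n_cells, n_nodes = len(cell_names), len(nodes)
    psi_matrix = np.zeros((n_cells, n_nodes))
    for ci, cluster in enumerate(cell_clusters):
        for ni, node in enumerate(nodes):
            psi_matrix[ci, ni] = psi_spec[(node, cluster)]
    total = rng.poisson(reads_per_node, size=(n_cells, n_nodes))
    inclusion = rng.binomial(total, psi_matrix)
    exclusion = total - inclusion
    idx = pd.Index(cell_names, name="cell")
    cols = pd.Index(nodes, name="node")
    inc = pd.DataFrame(inclusion, index=idx, columns=cols)
    exc = pd.DataFrame(exclusion, index=idx, columns=cols)
    truth = GroundTruth(
        barcode_to_cell={},
        cell_species={},
        cell_s_phase={},
        cell_cluster={"splice": dict(zip(cell_names, cell_clusters))},
        read_truth=pd.DataFrame(),
        molecules=pd.DataFrame(),
        barcode_read_totals=pd.Series(dtype=np.int64),
        n_rrna_reads=0,
        node_psi=dict(psi_spec),
    )
    return inc, exc, truth


# ---------------------------------------------------------------------------
# writers


def write_reads_table(reads: pd.DataFrame, path: str) -> None:
    """Tab-separated aligned-record table (stand-in for a BAM).

    Columns: read_id, barcode, ufi, chrom, strand, block_starts, block_ends
    (comma-joined, 0-based half-open).
    """
    out = reads.copy()
    out["block_starts"] = [",".join(str(s) for s, _ in b) for b in out["blocks"]]
    out["block_ends"] = [",".join(str(e) for _, e in b) for b in out["blocks"]]
    out.drop(columns=["blocks"]).to_csv(path, sep="\t", index=False)


def read_reads_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    blocks = [
        tuple(zip((int(s) for s in ss.split(",")), (int(e) for e in es.split(","))))
        for ss, es in zip(df["block_starts"], df["block_ends"])
    ]
    df = df.drop(columns=["block_starts", "block_ends"])
    df["blocks"] = blocks
    return df
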