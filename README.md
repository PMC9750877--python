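# sctotal

Analysis toolkit for single-cell **total** RNA-seq — protocols that fragment
and poly(A)-tail all RNA before barcoding, so that reads cover whole gene
bodies and capture non-polyadenylated species (canonical histones, snoRNA/
snRNA/miscRNA) that 3′-capture methods miss. The package implements the
computational pipeline such an experiment needs, end to end, together with a
synthetic-data generator that plants ground truth for every stage, so the
whole pipeline is testable without any sequencing download.

It is written for computational biologists who work in Python with
`AnnData`/`scanpy` containers and want the method-specific steps — not the
generic scRNA-seq plumbing — as a tested, importable library.

## What it implements

**Barcode calling** (`sctotal.barcodes`). Cells are separated from ambient
barcodes on the histogram of log₁₀(reads per barcode): a degree-10
polynomial is fitted to the binned histogram and the threshold is the valley
(local minimum between two modes) at the largest log₁₀-read position.
Observed barcodes merge into a whitelist entry when the assignment is
*unique* within a maximum Hamming distance (2 for 16-nt droplet barcodes,
1 for the 384 8-nt plate barcodes). PCR duplicates collapse by
(cell, UFI, gene) identity, where the UFI is the per-fragment random tag.

**Read assignment** (`sctotal.feature_counting`). After in-silico rRNA
depletion, each aligned read passes a fixed hierarchy:

1. contact with a TEC transcript → discarded;
2. fully inside an intron-free small-RNA annotation → that feature;
3. overlapping several genes: exonic hits beat intronic ones; surviving ties
   become a composite feature named by all tied genes;
4. reads in introns or across exon–intron junctions are **unspliced**, reads
   exclusively in exons are **spliced**;
5. within one (cell, gene, UFI) molecule, one unspliced read makes all of
   its reads unspliced.

Molecules are counted per (cell, feature, UFI, status) into an `AnnData`
with separate `spliced`/`unspliced` layers; the per-cell unspliced fraction
u/(u+s) is the substrate for RNA-velocity methods.

**QC** (`sctotal.qc`). Barnyard species calls (singlet if one species holds
> 75% of ≥ 7,500 UFIs, else doublet), per-timepoint cell filters (read
floors 10⁴/10³·⁵/10³·⁵/10³ for E6.5–E9.5, transcript ceiling 10⁶, biotype
windows 85–95% protein-coding, 1–3% lncRNA, 5–15% small RNA), and binomial
per-cell downsampling for gene-detection saturation curves.

**Cell cycle** (`sctotal.cell_cycle`). Canonical histone genes are
non-polyadenylated and S-phase-restricted, so the per-cell histone molecule
count is bimodal. Cells with more than 35 histone molecules are called
S-phase; a two-component Weibull mixture fitted by EM (weighted
maximum-likelihood updates, likelihood asserted monotone) describes the
bimodality and can propose the threshold as the equal-posterior crossing
w₁f₁(x) = w₂f₂(x) between the modes.

**Graphs and clustering** (`sctotal.graph_embedding`). Counts are
library-size normalized to 10⁴ and log(1+x)-transformed; covariates (depth,
cell-cycle) are regressed out per feature with OLS and z-scaled. In PCA
space each cell connects to its ten nearest neighbors (Manhattan metric);
an edge survives only if d < mean + 1.5·s.d. over all k·n candidate
distances. A temporal variant links each cell to 30 neighbors among its own
and the previous timepoint, projected into the later timepoint's PCA basis.
UMAP/Leiden/PAGA are delegated to their standard implementations, with a
degree-corrected edge-count statistic as a documented fallback for
cluster connectivity.

**Label transfer** (`sctotal.label_transfer`). To compare two technologies,
cells are co-embedded (technology and depth regressed out) and each target
cell takes the cluster of its nearest reference cell with score
s = P(background ≥ d) — the survival function of the reference cluster's
first-NN distances into the target technology. Low-scoring cells are
excluded; bidirectionally consistent assignments form *equivalent clusters*,
the unit for marker comparison. Markers use Welch t-tests with
log₂FC = log₂((m_A+c)/(m_B+c)), c the minimum positive mean.

**Differential splicing** (`sctotal.splicing`). A splicing node's inclusion
rate is ψ = inclusion/(inclusion+exclusion), quantified from ≥ 10 reads.
For a cluster pair, random pseudo-bulks (≤ 200 cells) are drawn repeatedly;
each repetition yields a posterior probability that |ψ_A−ψ_B| exceeds a
minimum shift (Jeffreys beta contrast). The repetition probabilities are
summarized by a method-of-moments beta fit; a node is a **DISN**
(differentially included splicing node) when the beta CDF at 0.95 is ≤ 0.05.
A node is an **SNM** (splice-node marker) of a cluster when ≥ 2 of its
pseudo-bulks have |Z| with P ≤ 0.05 against all other pseudo-bulks and the
cluster's mean ψ deviates by ≥ 0.3.

**Synthetic data** (`sctotal.synthetic_data`). Generates everything above
with planted truth: a toy two-species annotation (multi-exon protein-coding
genes, single-exon non-polyA histones, lncRNAs, a snoRNA nested in a host
intron, rRNA, TEC, one exonic-over-intronic and one exonic-over-exonic
overlap), reads with a bimodal depth distribution, geometric PCR copies,
barcode substitution errors, planted unspliced status, bimodal histone
content, species doublets, two technologies over shared clusters, and
splicing nodes with cluster-specific ψ.

## Worked example

```bash
python examples/07_end_to_end.py
```

```
knee threshold log10(reads) = 2.50; cell recovery 100.0%
rRNA depletion: {'input': 70265, 'removed': 3455, 'retained': 66810}
count matrix: (80, 68), 33367 molecules
mean unspliced fraction: 0.436
S-phase cells called: 56 of 80 (histone score > 35)
Leiden clusters: 6
cells transferred across technologies: 252
DISNs: 10 of 30 nodes; SNM flags: 20
rerun byte-identical: True
```

Reading the output: the knee at log₁₀(reads) = 2.50 separates the 80
planted cells from 500 ambient barcodes (100% recovered); rRNA depletion
removes exactly the planted rRNA reads; the unspliced fraction ≈ 0.44
matches the planted nascent-RNA share; 56/80 cells exceed the 35-molecule
histone threshold (planted S-phase fraction 0.65); all 10 nodes planted
with a ψ shift of 0.4 are called DISNs with no false calls on the 20 null
nodes, and each is flagged as an inclusion marker in one cluster and an
exclusion marker in the other (20 SNM flags). The rerun digest confirms the
whole study is reproducible from the seed. The other `examples/` scripts
walk through each capability separately.

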