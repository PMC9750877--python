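# Methods

This note documents the models and procedures `sctotal` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Barcode knee detection

Input is the per-barcode raw read count. The histogram of log₁₀(reads) over
100 equal-width bins is fitted with a degree-10 least-squares polynomial and
the fitted curve is scanned on a 1,000-point grid for local minima. Only
*valley* minima are eligible — minima lying strictly between two interior
local maxima of the curve. The threshold is the valley at the largest
log₁₀-read position; barcodes strictly above it are accepted.

The valley restriction is the one numerical refinement over the plain
"highest-position minimum" rule: a degree-10 polynomial necessarily rings at
the histogram boundaries, and on a clean bimodal histogram the literal rule
returns a boundary artifact beyond the cell mode (on the default synthetic
conditions: threshold 3.97 instead of ≈ 3.03, destroying cell recovery). A
valley between two modes is what a knee *is*; boundary dips separate
nothing. Degenerate inputs (all counts equal, or no valley at all) raise a
`UnimodalHistogramError` so the caller can fall back to a fixed threshold.
A genuinely unimodal but noisy histogram is still a known failure mode: the
polynomial can hallucinate two shallow modes with a valley between them, and
no test claims otherwise.

Defaults — degree 10, 100 bins, 1,000 grid points — are this package's
choices; the underlying procedure is usually described without them. All
three are arguments.

## Barcode merge and deduplication

An observed barcode is assigned to a whitelist entry only when exactly one
entry lies within the maximum Hamming distance (2 for 16-nt droplet
barcodes, 1 for 8-nt plate barcodes); zero or several candidates leave the
read unassigned. Ambiguous merges are discarded rather than tie-broken by
abundance, because a non-unique assignment is evidence, not noise.
Duplicate removal collapses reads sharing (cell, UFI, gene assignment) to
one molecule; equal UFIs on different genes are distinct molecules.

## Read assignment hierarchy

Rules, in priority order, applied per read against same-strand genes (the
chemistry is stranded; `strand_mode="ignore"` is available):

1. any block contact with a TEC gene discards the read;
2. a read with *every* block inside a single intron-free small-RNA
   annotation (miscRNA, mtRNA, mt-tRNA, TrJGene, miRNA, rRNA, ribozyme,
   sRNA, scaRNA, snRNA, snoRNA) is assigned to it, with no
   spliced/unspliced status; partial overlap falls through;
3. among remaining overlapping genes, genes containing all blocks within
   their exon union ("exonic" hits) take precedence over intronic ones;
   surviving ties produce a composite feature named by the tied genes'
   names, alphabetically sorted, joined with "–";
4. exonic-only reads are spliced; reads touching an intron or an
   exon–intron boundary are unspliced;
5. within each (cell, feature, UFI) group, one unspliced member makes the
   whole group unspliced — the fragment demonstrably came from an
   incompletely spliced molecule.

Molecules are distinct (cell, feature, UFI, status) combinations after
rule 5. Small-RNA molecules carry no status and are counted in the spliced
layer so that layer sums equal molecule totals; the per-cell unspliced
fraction u/(u+s) is computed over intron-bearing biotypes only, excluding
them.

rRNA depletion runs before assignment as an interval filter: any read with
a block overlapping an annotated rRNA interval is removed and counted.

3′-terminal restriction (used for comparisons against 3′-capture data)
keeps reads whose midpoint, projected into cumulative exonic coordinates,
falls in the 3′-terminal fraction of the gene's spliced length
(strand-aware; positions inside introns inherit the offset of the upstream
junction). The fraction defaults to 0.2 and is exposed as a parameter
because the two published phrasings of this filter ("80 % 3′ end" vs "20 %
terminal portion") do not pin down a single number.

## Species-mixing QC

Per barcode, UFI totals per species: total < 7,500 → discarded; majority
share > 0.75 → singlet of that species; otherwise doublet. This is the
UFI-unit reading; the equivalent phrasing "more than 25 % of UFIs from the
other species → doublet" is the same rule. A gene-unit variant exists in
some descriptions; the `species_names` columns can carry gene counts
instead of UFI counts if a caller prefers that unit. The 7,500 floor is
applied to the combined total, before any per-species disambiguation.

Cell filtering uses per-timepoint log₁₀ read floors (E6.5: 4.0; E7.5/E8.5:
3.5; E9.5: 3.0), a 10⁶ transcript ceiling, and biotype-fraction windows
(protein-coding 85–95 %, lncRNA 1–3 %, small RNA 5–15 %). Downsampling
thins every count of cell *i* binomially with p = target/input — per-cell
binomial rather than global multinomial, matching the per-cell input/target
framing — and `genes_detected` counts features with ≥ 1 molecule, excluding
composite features because they are not uniquely assigned.

## Histone cell cycle

The histone score is the per-cell molecule total over flagged histone
features, both layers. Classification is `score > 35` (strict), a raw-count
rule — so the Weibull mixture is fitted to raw scores too, not to
normalized expression; the 35 threshold would be meaningless on any other
scale.

The two-component Weibull mixture is fitted by EM: E-step responsibilities
from the weighted component densities; M-step weighted Weibull
maximum-likelihood per component, solving the profile equation for the
shape by Brent's method and setting the scale in closed form. Zero scores
are offset by +0.5 before fitting (Weibull support is (0, ∞)); the fit is
diagnostic, classification always uses raw counts. Initialization is a
median split of the scores, with 5 restarts jittering the split quantile
(seeded); the best likelihood wins. The observed-data log-likelihood is
asserted non-decreasing at every iteration (tolerance 10⁻⁸ relative) — a
violated assertion means a broken M-step, not noise. Components are
reported in ascending scale order. Fewer than 50 positive scores, or
zero-variance scores, are rejected.

`suggest_threshold` returns the equal-posterior crossing w₁f₁(x) = w₂f₂(x)
between the two component scales (grid scan + Brent refinement; the
crossing nearest the high mode when several exist). On the generator's
study conditions it lands in the valley and agrees with the fixed rule.

Cycle-gene discovery is a per-gene two-sided Welch t-test between S and
non-S cells with the pseudo-count fold-change rule below; P values are
reported uncorrected (matching common practice for these screens) with a
Benjamini–Hochberg column alongside.

## Expression processing and graphs

Normalization: counts·10⁴/cell-total, then log(1+x). Zero-total cells are
an error, not a silent drop. The linear normalized matrix is kept as a
layer because fold-change rules are defined on linear means.

HVG selection delegates to scanpy's dispersion method (seurat flavor)
within the mean-log window [0.0125, 5], minus an exclusion list (cell-cycle
genes). Covariate regression fits, per feature, an OLS model with intercept
on the covariate matrix and keeps z-scaled residuals (ddof = 1; constant
features → zero vectors).

kNN graph: Manhattan distances in PCA space (50 components by default, 20
for very small datasets); each cell's k = 10 nearest neighbors (ties broken
by cell id via stable argsort — the reason this is hand-rolled over a
library NN search, whose tie order is not contractually stable). The edge
filter is global: threshold = mean + 1.5·s.d. (n−1 denominator) over all
k·n candidate distances, strict inequality. When the s.d. is zero the
strict rule would delete every edge of a perfectly uniform graph, so that
degenerate case keeps all edges: the filter exists to prune outliers and a
zero-spread distance set has none. Isolated cells are removed; the
undirected graph is the union of directed edges.

Temporal graph: for each timepoint t, cells of t and t−1 are projected into
t's PCA basis (fitted on t's cells) and each cell of t takes 30 nearest
neighbors in that pool; the earliest timepoint connects only within itself.
No distance filter; by construction no edge spans more than one step.

Leiden (resolution 1, seeded, weights 1/(1+d)) and UMAP are thin delegated
contracts. Cluster connectivity delegates to PAGA on the graph; the
fallback `edge_connectivity` statistic — observed inter-cluster edge count
over its degree-preserving expectation deg_a·deg_b/(2m) — is a documented
approximation used only when the delegated call is unavailable, and is
checked to agree with PAGA in ranking on synthetic graphs.

## Cross-technology transfer

Both technologies are co-embedded: concatenate, normalize, regress out
technology indicator and depth, PCA, Manhattan metric. For each reference
cluster the background sample is each member cell's first-NN distance into
the target technology. A target cell is assigned the cluster of its nearest
reference cell with score s = (#background ≥ d)/#background — the
empirical survival function. This orientation is chosen over the ECDF
reading of the ambiguous "area under the left curve" description because it
is the one under which *excluding low-score cells* makes sense: a low
survival score means the cell is farther from the cluster than essentially
all of its background, i.e. unreliable. The ECDF orientation remains
available (`mode="ecdf"`). The exclusion threshold defaults to 0.05; no
published value exists for it. The score is a rank statistic: invariant
under any strictly monotone transform applied jointly to d and the
background, and monotone non-increasing in d.

One behavior worth knowing: when one technology is noisier (lower depth),
its peripheral cells sit farther from the reference cloud than the
reference→target background suggests, so an asymmetric fraction of cells
can score below 0.05. Those are exactly the cells the score exists to
exclude; accuracy is defined over scored cells.

Equivalent clusters are label pairs (cluster in technology 1, cluster in
technology 2) supported — natively on one side, by transfer on the other —
by at least `min_cells` cells in *both* technologies; germ-layer annotation
attaches by the reference technology's published labels. Marker tables per
group use Welch t-tests and log₂FC = log₂((m_A+c)/(m_B+c)) with c = the
minimum positive mean across features and groups, on linear-scale means;
features all-zero in both groups are excluded because the test is undefined
there.

## Differential splicing

ψ = inclusion/(inclusion+exclusion), defined only from ≥ 10 supporting
reads. Pseudo-bulks are seeded random partitions of a cluster's cells into
n ≥ 3 groups of ≤ 200, sizes differing by at most one; clusters larger than
the total capacity are subsampled.

DISN calling, per cluster pair: each of 50 repetitions draws one random
pseudo-bulk per side, pools its counts, and computes the posterior
probability that |ψ_A − ψ_B| > Δψ_min (default 0.1) by Monte-Carlo contrast
of the two Jeffreys posteriors Beta(inc+½, exc+½) (2,000 paired draws,
seeded). The upstream quantifier's internal probability model is *not*
reimplemented — the repetition probabilities only feed the aggregation that
defines a DISN, so any calibrated posterior contrast serves. The 50
probabilities are clamped to [10⁻³, 1−10⁻³], fitted by method-of-moments
beta, and the node is a DISN when BetaCDF(0.95; α, β) ≤ 0.05 — i.e. when at
least ~95 % of the fitted mass lies above 0.95. The evaluation point 0.95
is a declared default (the aggregation is usually described without it);
uniform probabilities give CDF ≈ 0.95 and are correctly not called. Δψ
summaries (mean, s.d., variance across repetitions) are reported per node.
Nodes unquantified in any repetition on either side are skipped rather than
imputed. The whole procedure is symmetric in (A, B) up to the sign of Δψ.

SNM calling: a node is eligible once quantified (≥ 10 reads) in ≥ 50
pseudo-bulks across all clusters jointly (the floor is read as global, not
per repetition). For each cluster, each of its pseudo-bulk ψ values gets
Z = (ψ_b − μ_others)/σ_others against the mean and n−1 s.d. of all *other*
clusters' pseudo-bulks; the flag requires ≥ 2 bulks with two-sided normal
P ≤ 0.05 **and** |cluster mean ψ − μ_others| ≥ 0.3. The deviation is
measured against the other pseudo-bulks' mean — the same background the
Z-scores use — which is also the reading under which the canonical worked
example (cluster bulks at ψ 0.9 against others at 0.3 ± 0.05) yields its
stated deviation of 0.6. Zero spread in the background skips the node.
Direction is the sign of the deviation: inclusion vs exclusion marker.

Cluster pairs to compare are those with graph connectivity ≥ 0.05, each
unordered pair once.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the pipeline's rules
depend on, with planted truth for every quantity:

* **Annotation**: two species chromosomes; multi-exon protein-coding genes;
  single-exon non-polyadenylated histones; two-exon lncRNAs; intron-free
  small RNAs with one snoRNA nested strictly inside a host intron; rRNA
  intervals; a TEC gene; one exonic-over-intronic and one exonic-over-exonic
  gene pair (this is why ≥ 5 protein-coding genes per species are required).
  Coordinates are 0-based half-open throughout.
* **Depth**: per-barcode reads log-normal — cells at 10^3.6 (σ = 0.15 in
  log₁₀), ambient at 10^2.3 (σ = 0.25), i.e. a ~20× separation placing the
  valley near log₁₀ ≈ 3.0. Ambient totals are exposed without emitting
  reads, so knee-level checks run at full scale cheaply.
* **Molecules**: genes drawn from a Dirichlet-weighted per-species profile;
  geometric(p = 0.5) PCR copy counts (mean 2 reads/molecule); UFIs drawn
  *without replacement* within each (cell, gene) so planted molecules
  survive UMI collapsing exactly; 5 % rRNA molecules; barcode substitution
  errors at 0.005/nt. A planted 44 % of status-bearing molecules is
  unspliced, with the per-cell Bernoulli rate rescaled so single-exon
  histone molecules (always spliced) do not dilute the target. Some
  unspliced molecules emit one exon-only PCR sibling, so UFI propagation has
  real work to do.
* **Cell cycle**: S-phase fraction 0.65; histone molecules Poisson with
  mean 80 (S) vs 8 (non-S) — modes a raw-count threshold of 35 cleanly
  separates.
* **Doublets**: 3 % of cell barcodes mix the two species with a mixing
  fraction uniform on (0.35, 0.65) (two cells of comparable size); singlet
  cross-contamination 2 %. The barnyard-scale generator emits per-barcode
  species UFI totals directly.
* **Technologies**: two samplings of the same planted clusters (150 cells
  per cluster per technology) with log-normal profiles, an 8× marker-gene
  boost per cluster, 2× depth difference and a 3× down-weighting of the
  last third of genes in the second technology (standing in for 3′-capture
  losing non-coding RNA).
* **Splicing**: per cell and node, totals Poisson(20) and inclusion
  Binomial(total, planted ψ of the cell's cluster).

Where no external value existed, these defaults were chosen once as
realistic for the kind of experiment emulated and are not tuned per test.

Deliberately **not** emulated: nucleotide content beyond barcodes/UFIs,
base qualities, alignment error, mapping ambiguity, gene-length and GC
biases, ambient-RNA contamination *within* cell barcodes, empty-drop
expression profiles resembling cell mixtures, and UMI errors. Passing tests
therefore demonstrate that the *rules and statistics* are implemented
correctly and recover planted structure — not that they are robust to
alignment artifacts or to ambient profiles that mimic real cells.

Two scale constraints matter when configuring the generator:

* The planted unspliced share is achievable only while multi-exon molecules
  outnumber 0.44× the status-bearing molecules per cell; at very shallow
  depth the fixed S-phase histone mode (80 molecules) violates this and the
  realized share drops below target. Scaled runs therefore use cells of
  ~10^2.9 reads, not less.
* UFI space is 4⁶ = 4,096 per (cell, gene); a cell may not exceed that many
  molecules of one gene (enforced with an explicit error).

## Problem sizes

Tests and the acceptance script run the study scaled down so the whole
suite completes in well under a minute of simulation time per component:
end-to-end runs use 80 cells / 500 ambient barcodes at 10^2.9 reads per
cell; counting checks use 50–200 cells; knee checks run at the full default
scale (5,500 barcodes) on totals; DISN calling uses 10 repetitions instead
of 50 (the aggregation is the same; only the beta fit's sample size
changes); SNM checks use 60 pseudo-bulks. These sizes are the package's
own choices for a reproducible desk-scale study.

## Known limitations

* The knee detector assumes the ambient and cell modes are separable on the
  log₁₀ histogram; overlapping modes shift the valley and no confidence
  measure is attached.
* `assign_reads` is a per-read Python loop over an interval index — fine at
  desk scale (tens of thousands of reads per second), not a BAM-scale
  implementation.
* The EM fit can collapse one Weibull component on unimodal data (weight
  < 0.05); callers should compare against the 1-component fit before
  interpreting the mixture.
* The fallback connectivity statistic matches PAGA's *ranking*, not its
  values; `select_pairs` thresholds are calibrated against the delegated
  PAGA output.
* `differential_inclusion_once` is a calibrated stand-in for the upstream
  splice-graph quantifier's probability model, adequate for the aggregation
  that defines DISNs but not a reimplementation of it; node classes other
  than CE/RI are carried as labels on provided counts.
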