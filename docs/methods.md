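# Methods

## Data model

Counts live in a sparse genes × cells integer matrix with unique,
case-sensitively matched gene symbols (zebrafish symbols are lowercase;
case distinguishes orthologs across species). Per-cell annotation is a
tab-separated table keyed by `cell_id` with `sample_id`, `condition` and
optional `cluster` columns; unknown columns pass through untouched.
Ligand–receptor knowledge is a two-column pair table; a small built-in
zebrafish demo table (bdnf→ntrk2, bdnf→ngfra, il4→il4r.1) covers the
documentation examples. Readers reject malformed input (dimension
mismatches, negative or fractional counts, duplicate identifiers) rather
than coercing it.

## Quality control and normalization

Cells are kept when all three hold: 1,000 ≤ UMIs ≤ 15,000,
500 ≤ detected genes ≤ 2,500, and mitochondrial fraction ≤ 6%. The
published wording of such windows ("more than X to Y") is ambiguous
about endpoint inclusion; we read both windows as closed intervals and
expose every bound as a parameter so the open reading is one flag away.
The mitochondrial fraction is a fraction of *counts* on `mt-`-prefixed
genes, not a fraction of genes — the standard droplet-QC usage. No
dedicated doublet detector is included; the upper gene bound is the only
multiplet guard, because no algorithm beyond that bound is specified for
this workflow. After cell filtering, genes detected (count > 0) in fewer
than 5 remaining cells are dropped. Filtering is idempotent on realistic
data and that property is asserted on the shipped fixture.

Normalization is `ln(1 + s·c/total)` with scale factor s = 10⁴, applied
to nonzeros only so sparsity is preserved. Variable genes are ranked per
sample by the dispersion (variance/mean) of the de-logged values,
z-scored within 20 equal-frequency mean bins (the classic
mean–variability-plot family); with very small gene sets the bin count
shrinks so bins keep ≥ ~10 genes, otherwise every z-score would collapse
to zero in singleton bins. The top 1,000 per sample are merged with
per-sample provenance.

## Differential expression

The test is the two-sided Wilcoxon rank-sum. For pooled sample sizes up
to 12 without ties the exact null distribution is used; otherwise the
normal approximation with tie and continuity corrections (completely
tied inputs give p = 1). The effect size is the Seurat-convention
average log fold change: natural log of the de-logged group means with
pseudocount 1. DEG calling keeps genes expressed in ≥ 10% of either
group (min.pct guard against near-empty genes, settable to 0 for strict
replication) with raw p < 0.05 and |avg_logFC| ≥ 0.25. No FDR is applied
at the DEG stage — deliberately, because the workflow this implements
thresholds raw p there — while marker detection (below) applies BH-FDR
at 0.1. Both groups must contain ≥ 3 cells.

Subpopulation "dissection" selects cells with *raw count > 0* of a named
receptor gene, optionally within a cell-type scope. Count positivity is
the minimal reading of "receptor-positive" and is deliberately
threshold-free; a different cutoff can be applied by pre-filtering.
Reciprocal genes between two treatment arms are those present in both
DEG tables with opposite-signed fold changes.

## Cell typing and label transfer

Markers are one-vs-rest DEG tables per cluster with BH-FDR within each
cluster's test family; only positively elevated genes (higher expressing
fraction or positive fold change) are reported, since markers serve as
identity features. Clusters under 3 cells are skipped with a warning.
Top-5 ranking breaks ties by higher avg_logFC, then lower p, then gene
symbol, so outputs are reproducible. Label transfer trains a random
forest (500 trees, class-balanced bootstrap, fixed seed) on the union of
top-5 markers at FDR < 0.1; 500 trees is a stability choice, recorded in
the model object, as the underlying workflow names only the algorithm
family. Query cells are *predicted*, never re-clustered — cross-sample
alignment and de novo graph clustering are out of scope, and cluster
labels are pluggable inputs (or simulated truth). Missing feature genes
in a query are imputed as zero with a warning; all-zero cells are
flagged and carry low vote confidence.

## Interaction maps

The single most consequential unstated constant in cluster-level
ligand–receptor mapping is when a cluster counts as "expressing" a gene.
Default: ≥ 10% of the cluster's cells and ≥ 3 cells with nonzero counts
(echoing the 3-cell rule used elsewhere in the pipeline); both numbers
are mandatory, logged parameters of every output. Edges are binary
presence/absence calls — the mean normalized expression of the endpoints
is carried only as an annotation — because the downstream object is a
three-colour arrow diagram, not a weighted network. Maps can be anchored
at a ligand (all its receptors) or at a receptor (all its ligands).
Differential classification is pure set algebra per treatment-vs-control
pair: unchanged = in both, lost = control only, gained = treatment only;
it partitions the union, is order-independent, and raising the
expression threshold can only remove edges. An optional
differential-expression requirement on the endpoint genes is *not*
applied by default: an edge counts when both ends are expressed,
matching the literal mapping criterion. Statistical edge significance
(permutation tests à la CellPhoneDB) is a non-goal.

## Overlap statistics

Receptor-defined subpopulation overlap reports only-A/only-B/both counts
with percentages over the union of cells positive for at least one of
the two genes — the reading under which published three-way percentages
sum to 100; the positive-count denominator can be derived from the
returned counts if wanted. DEG-list overlap uses the same union
denominator. The over-representation test is the one-sided
hypergeometric upper tail, exact by construction (verified against
exhaustive enumeration for universes ≤ 25 genes), with BH-FDR reported
alongside raw p. The universe is a mandatory, logged argument; the
natural default is all genes surviving QC.

## The simulator

`crosstalk.sim` draws counts from a negative binomial with mean =
(per-type gene program) × (condition factor) × (per-cell size factor)
and inverse-dispersion r = 2; size factors are Gamma(shape 3, mean 1),
and r = ∞ gives the Poisson limit. Mitochondrial load re-allocates a
per-cell fraction, uniform on [0.02, 0.07], of the expected depth onto
`mt-` genes, so a realistic minority of cells violates the 6% cap. The
demo design has five populations (htr1d+ neurons, PC0, PC2, immune,
oligodendrocytes), four conditions, ten exclusive 8× markers per
population, ~1,800 background genes at a target depth of ~3,500
UMIs/cell, and 250 cells per population per condition — desk-scale
numbers chosen so that QC, typing and edge calling all operate in their
intended regimes while the full suite runs in well under a minute per
stage. Planting an edge gain (loss) moves both endpoint genes' expected
counts across the cluster-expression threshold between control and
treatment, with wide margins (expected expressing fraction ≈ 0.56 when
on, ≈ 0.02 when off, against the 0.10 rule).

The ground-truth ledger is derived *analytically* from the design: an
edge is truly active when both endpoints pass the expression rule in
expectation (size factor 1), over all cluster pairs — not only the
declared ones — so spurious edges are judged against the complete truth.
Gamma size-factor variability makes the realized expressing fraction
deviate slightly from the analytic one; the planted margins dwarf this
error.

What the simulator does not emulate: ambient RNA, doublets, batch
effects beyond per-sample size factors, gene–gene correlation within a
program, and UMI saturation. Passing tests therefore demonstrate that
the *inference rules are implemented correctly and recover planted
structure under NB noise*, not that the defaults are optimal for any
particular real tissue.

## Replication from supplementary tables

Published DEG supplements arrive as XLSX with heterogeneous headers.
The reader auto-detects gene/fold-change/p/FDR columns by
case-insensitive header heuristics (exact match first, then substring),
logs the mapping, and falls back to the first column for the gene
identifier, since the identifier namespace of such files is not
standardized. Directional counts, unique-gene counts (optionally after
re-applying p < 0.05 and |logFC| ≥ 0.25, so the filter used upstream can
be identified empirically) and pairwise overlaps all route through the
same code as the synthetic pipeline. The original supplements are not
redistributable, so tests exercise this path on synthetic spreadsheets
written at test time.

## Numerical and degenerate-input choices

Zero-total cells get mitochondrial fraction 0 and an explicit flag;
normalization refuses matrices containing them. Vectorized rank-sum
columns that are completely tied get p = 1 instead of NaN. Hypergeometric
p for an empty gene set is 1. DEG tables sort by |avg_logFC| descending
with the gene symbol as the tiebreak; edge lists and differential maps
sort lexicographically — every output is deterministic given the seed,
and all randomness (simulation, forest training) flows from explicit
integer seeds.

## Known limitations

Edge calling has no significance statement, so very small clusters near
the 10%/3-cell boundary can flip edges between runs of different seeds.
Label transfer presumes the query contains only reference-like types; a
novel population is silently absorbed into its nearest class (flagged
only indirectly by low confidence). The exact rank-sum path is limited
to 12 pooled observations without ties; beyond that the tie-corrected
normal approximation is used, which is accurate at the group sizes where
it is invoked but approximate nonetheless.
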