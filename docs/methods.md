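# Methods

This note documents the statistical models, the numerical choices and the
simulator behind `clonetrace`, and the design decisions taken where the
field's practice is not uniform.

## Barcode resolution

A cell index may match several barcode sequences (sequencing error, ambient
barcodes, genuine double labelling). Source studies resolve this with
study-specific rules; `clonetrace` uses a single parameterized **dominance
policy**: sort a cell's barcodes by count (ties broken lexicographically on
barcode id), keep the cell iff the top count is ≥ `min_dominance` × the
runner-up (default 2) and ≥ `min_count` (default 1). Ties at the default
dominance fail and the cell is dropped. The rule is per-cell, hence
idempotent and independent of input order, and the number of resolved cells
is monotone non-increasing in `min_dominance`. We chose one documented rule
over per-study mimicry for the sake of reproducibility; both parameters are
exposed.

High-confidence clone filtering removes barcodes that labelled more than
one cell at the initial barcoding stage (such a barcode marks several
progenitors, not one clone). Filtering requires explicit initial-stage
counts; without them the clone matrix is passed through unchanged — we do
not infer multi-progenitor status heuristically from late time points.

## Fate map and fate bias

The clone matrix counts **cells** per clone × cell type (not UMIs). The
fate map divides each row by its sum; rows are exact probability vectors
(verified to 1e-9) and invariant to scaling a clone's counts.

Fate bias for clone β and target set T uses the 2×2 table
a = cells of β in T, b = cells of β elsewhere, c = other cells in T,
d = other cells elsewhere, and the one-sided (enrichment) Fisher exact
test, p = P(X ≥ a) for X ~ Hypergeometric(N, a+c, a+b). Choices:

* **Sidedness.** Enrichment-sided, because fate bias is an over-occupancy
  question; a two-sided variant is available on the test function.
* **Exact arithmetic.** The p-value is a ratio of integer sums of binomial
  coefficients (`math.comb`), so it agrees with exhaustive enumeration to
  one floating-point rounding. Clone sizes bound the number of terms, so
  this stays fast even for matrices with thousands of cells.
* **BH family.** All clone × target tests are pooled into one
  Benjamini–Hochberg family (per-target stratification available via
  `bh_scope="per_target"`). The BH implementation is the literal step-up
  formula.
* **Labelling.** A clone is labelled by the target of its minimum-FDR
  significant enriched test (FDR < α, odds ratio > 1); ties break by larger
  in-target count, then lexicographic target name; otherwise "balanced".
  Targets default to one singleton set per cell type; named groupings
  (e.g. lymphoid = {T, B, NK}) can be supplied as a mapping / YAML file.
* **Minimum clone size 2.** A single cell cannot evidence bias; size-1
  clones are reported as "untested" and excluded from summaries.
* Fate-bias fractions are reported both clone-weighted and cell-weighted,
  since published summaries do not always state the weighting.

## Lineage relationships

"Barcode signatures" are the raw per-clone count vectors of each cell type
(ranks make raw vs row-normalized nearly equivalent; a `use="fate_map"`
flag switches). Spearman ρ is Pearson on average ranks (tie-aware);
constant vectors get ρ = 0 with a warning rather than NaN. For each pair of
cell types, clones with zero cells in both members are excluded
(`universe="pairwise"`, default) because an all-zero pair carries no
ordering information; `universe="global"` keeps every clone. The
dendrogram is average-linkage clustering of d = 1 − ρ (complete/single
available); the emitted Newick tree is ultrametric with child branch
lengths (parent height − child height)/2, so a two-type tree is
`(A:h,B:h);` with h = (1 − ρ)/2.

## Differential features between fate biases

Cells of one cell type are split by their clone's fate-bias label. Library
sizes are normalized as per-cell total counts over the median total; fold
changes are log₂ of normalized group means with a pseudocount of 1.

* **RNA: negative-binomial LRT.** NB2 regression (Var = μ + αμ²) with log
  link and log size-factor offset; parameters (intercept, group effect,
  log α) are maximized by L-BFGS-B from method-of-moments starting values;
  the group effect is tested by a 1-df likelihood-ratio χ² against the
  intercept-only fit. This is an explicit, specification-reproducible test
  rather than a re-implementation of any particular toolkit's "negbinom"
  option; on Poisson-like data it agrees with a Poisson GLM LRT within a
  few percent, its null size measures ≤ 0.07 at nominal 0.05, and it
  detects planted 4-fold changes at n = 100/group with > 95% power.
  All-zero features are reported as (log₂FC 0, p 1).
* **ATAC: Wilcoxon rank-sum.** Exact by enumeration of all C(n, n_a)
  group assignments (average ranks fixed from the pooled sample; two-sided
  as deviation of the rank sum from its mean) when n ≤ 12; otherwise the
  normal approximation with tie correction and a 0.5 continuity
  correction. At the n = 12 boundary the approximation is accurate to
  about one percentage point.
* **Significance flag.** Raw p < 0.05 and |log₂FC| > 0.5 (no multiplicity
  correction on the flag, matching common single-cell marker practice); a
  BH-adjusted column is emitted alongside for users who want it.
* Peak→gene annotation is reduced to nearest-TSS assignment from a
  user-supplied gene BED (`nearest_tss_genes`).

## Motif scanning and enrichment

PWM probabilities get a pseudocount of 0.008 (then column renormalization);
log₂-odds scores against a 0-order background are discretized on a 1e-3
grain. The null distribution of the window score under the background is
computed exactly by dynamic programming (convolution of per-position
4-point distributions); the match threshold is the smallest grid score
whose tail probability is ≤ `p_cutoff` (default 5e-5). If even the best
word's tail exceeds the cutoff the threshold is unattainable and the motif
never matches — e.g. a length-4 deterministic motif, whose perfect match
has null probability (1/4)⁴ ≈ 3.9e-3, can never match at 5e-5. A region
matches if any window on either strand reaches the threshold; the reverse
strand is scanned with the reverse-complemented PWM and its own threshold.
Windows containing N never match. Lowering the cutoff never adds matches.

Enrichment between disjoint foreground and background region sets is the
same one-sided hypergeometric test used for fate bias, BH-adjusted across
motifs; log₂ enrichment compares match rates with 0.5 pseudocounts. The
background base composition is estimated from the background sequences by
default (uniform optional). Not modelled: GC-matched background selection,
k-mer shuffling nulls, deviation-score frameworks.

## Synthetic experiments

The generator emulates a LARRY-style in vitro haematopoiesis experiment at
the ten-thousand-cell scale. Defaults (chosen once as the study
conditions): 2,000 clones; log-normal clone sizes (meanlog 1.1, sdlog 0.8,
mean ≈ 4 cells); seven cell types (HSPC 0.40, monocyte 0.15, neutrophil
0.15, erythroid 0.10, lymphoid 0.10, basophil 0.05, megakaryocyte 0.05);
30% biased clones placing 0.8 of their mass on one non-progenitor target
(remainder proportional to background); detection Bernoulli(0.8); 5%
multi-barcode cells whose spurious second barcode has a count uniform on
[1, primary]; 10% multi-progenitor barcodes (initial-stage count 2). Gene
counts are NB2 (Gamma–Poisson, dispersion 0.5) around log-normal gene
means with per-cell library factors on [0.7, 1.3]; planted DE genes shift
progenitor cells of clones biased toward the two designated contrast
targets by ±2 log₂-fold. Peak sequences are uniform-random 200-mers with a
consensus motif (`TGACTCAG`, 0.85 dominance) embedded in 80% of foreground
and 10% of background regions, alongside random decoy PWMs. One seed
spawns independent substreams per stage, so outputs are byte-identical
across runs of the same configuration.

Two derived configurations are used for benchmarking: `benchmark_config`
(300 clones, meanlog 3.4 / sdlog 0.4, so planted biased clones typically
retain ≥ 20 observed cells — the regime where a clone-level exact test has
power) and `null_config` (60 clones, four cell types, no planted bias) for
type-I-error studies; the type-I study uses 500 such datasets and the
recovery benchmark 20 seeds. These sizes are the package's benchmark
definition, stated here so results are comparable across machines.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: barcode sequencing error structure (assignments
are taken as given), transcriptome manifold structure (no cell-type
expression programs beyond the planted group shifts), clone-size
dependence on fate, batch effects, doublets, and GC/accessibility biases
in peak sequences. Recovery rates on real experiments will be lower than
on these benchmarks; the benchmarks establish correctness of the
statistics, not field performance.

## Numerical conventions and degenerate inputs

Odds ratios use ad/bc with ∞ when bc = 0 and ad > 0, 0 when ad = 0 and
bc > 0, NaN when both vanish. All-zero clone rows are dropped at read time
with a warning. Category order is first-appearance order and is preserved
in every output; all secondary sort ties break lexicographically on ids.
Result tables are TSV with floats at 6 significant digits; −log₁₀(p) is
capped at 300. Errors name the offending file, line, row or group wherever
the information exists.

## Known limitations

* The NB dispersion is estimated per feature with no shrinkage across
  features; at very small group sizes the LRT can be mildly anticonservative
  (measured ≤ 0.07 at nominal 0.05 with n = 50 per group).
* The Fisher test conditions on observed margins; clones related by
  lineage are treated as independent draws from the pooled background.
* Lineage ρ between types with few shared clones is noisy; pairs with
  fewer than three supporting clones return ρ = 0 with a warning.
* Motif enrichment compares raw match indicators; it does not correct for
  region length or composition differences between foreground and
  background beyond the 0-order background model.
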