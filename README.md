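# clonetrace

Clonal barcode analysis for single-cell lineage tracing (scLT).

In an scLT experiment a heritable DNA barcode marks each progenitor cell, so
every profiled cell carries both a molecular readout (transcriptome or
chromatin accessibility) and a clone identity. `clonetrace` takes the
barcode–cell assignments such an experiment produces and answers the
questions this kind of data exists for:

* **Clone statistics** — clone sizes, per-cell-type barcode diversity,
  barcode detection rate.
* **Fate outcomes** — the *fate map*, normalizing each clone β over cell
  types A: `value(β, A) = counts(β, A) / Σ_A counts(β, A)`.
* **Fate bias** — for each clone and candidate target cell-type set, a
  one-sided Fisher exact test of the clone's occupancy against random
  sampling of all barcoded cells, Benjamini–Hochberg adjusted over all
  clone × target tests; clones with FDR < 0.05 and odds ratio > 1 are
  called biased toward their minimum-FDR target.
* **Lineage relationships** — Spearman correlation of per-clone count
  signatures between cell-type pairs, with an average-linkage dendrogram
  (Newick) of `d = 1 − ρ`.
* **Fate-linked differential features** — negative-binomial LRT (RNA) or
  exact/asymptotic Wilcoxon rank-sum (ATAC) between cells grouped by their
  clone's fate-bias label; features with p < 0.05 and |log₂FC| > 0.5 are
  flagged.
* **Motif enrichment** — PWM scanning with exact dynamic-programming score
  thresholds at a background tail probability cutoff (default 5 × 10⁻⁵),
  then hypergeometric foreground-vs-background enrichment.
* **Synthetic experiments** — a generator that plants fate-biased clones,
  detection dropout, multi-barcode noise cells, multi-progenitor barcodes,
  differential genes and sequence motifs, with a full truth ledger, so the
  whole pipeline is testable end to end.

It is aimed at labs running LARRY-style lentiviral barcoding (or any
technology producing barcode–cell tables) who want a scriptable, fully
reproducible local counterpart to interactive clone-analysis portals.

## Worked example

Simulate a benchmark experiment (300 clones, 80%-biased clones among seven
haematopoietic cell types) and analyze its clone matrix:

```python
from clonetrace import (read_clone_matrix, clone_sizes, clone_fate_bias,
                        summarize_fate_bias, lineage_relationship, lineage_tree)
from clonetrace.fate import UNTESTED
from clonetrace.simulate import benchmark_config, simulate_experiment

simulate_experiment(benchmark_config(1), include_counts=False,
                    include_motifs=False, out_dir="demo")
m = read_clone_matrix("demo/clone_matrix.tsv")
print(clone_sizes(m).head(3))
calls = clone_fate_bias(m, alpha=0.05)
tested = [c for c in calls if c.label != UNTESTED]
print(summarize_fate_bias(tested))
```

which prints

```
  clone_id  size  n_cell_types
clone00156    97             7
clone00140    62             7
clone00082    60             6
               label  n_clones  fraction
     Basophil biased        19  0.063333
    Erythroid biased        12  0.040000
         HSPC biased         4  0.013333
     Lymphoid biased        21  0.070000
Megakaryocyte biased         9  0.030000
     Monocyte biased        12  0.040000
   Neutrophil biased        17  0.056667
            balanced       206  0.686667
```

— the largest clone spans 97 cells across all seven types; 31% of tested
clones are called fate-biased, matching the 30% planted by the generator.
The strongest call is a basophil-biased clone with 45 of its 53 cells in
basophils (2×2 table a,b,c,d = 45, 8, 610, 6897; odds ratio 63.6,
p = 1.7 × 10⁻⁴⁰, FDR = 3.7 × 10⁻³⁷). The lineage dendrogram for the same
matrix,

```
>>> print(lineage_tree(lineage_relationship(m)))
(Basophil:0.564921,(Lymphoid:0.503545,(Megakaryocyte:0.451504,
 (Erythroid:0.392638,(Neutrophil:0.344269,(HSPC:0.232398,
 Monocyte:0.232398):0.111871):0.0483694):0.0588657):0.0520412):0.0613755);
```

places HSPC closest to monocytes (ρ = 0.54), the most strongly coupled
pair in this simulation.

The same analyses are available from the shell:

```bash
clonetrace simulate --seed 1 --out demo/
clonetrace report --clone-matrix demo/clone_matrix.tsv --out results/
clonetrace fate --clone-matrix demo/clone_matrix.tsv --alpha 0.05 --out results/f
clonetrace motif --motifs demo/motifs.meme --fg fg.fasta --bg bg.fasta --out results/m
```

`clonetrace report` emits six tables (clone sizes, fate map, fate-bias
calls and summary, lineage correlation, Newick tree) and is bit-reproducible
for a fixed input.

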