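# lne — single-sample local network entropy

`lne` detects pre-disease (critical-transition) states from a **single
case sample** scored against a reference cohort on a protein–protein
interaction network, and derives stage-wise tipping points, dynamic
network biomarker (DNB) gene modules, and survival-stratified
prognostic biomarkers.

For each network gene the local entropy is the Shannon entropy (scaled
by 1/M) of the normalized absolute Pearson correlations between the
gene and its M first-order neighbors. A case sample is scored by mixing
it alone into the n reference samples and recomputing: the global score
is the mean over all Q network genes of |ΔE| · |ΔSD|, the product of
the per-gene entropy change and the change in the gene's standard
deviation. Aggregating per-sample scores along the clinical stage axis
yields a curve whose peak (or largest jump) is called as the critical
transition stage.

## Components

| module | purpose |
| --- | --- |
| `lne.network` | STRING-style edge-list parsing, confidence thresholding, pruning, first-order neighborhoods, SIF/GraphML export |
| `lne.expression` | genes × samples matrices plus reference/case/stage annotations |
| `lne.entropy` | per-gene local entropies and the global differential score |
| `lne.tipping` | stage-wise score aggregation and transition calling |
| `lne.biomarkers` | top-5% gene sets, common (DNB) genes, O-LNE / P-LNE prognostic classes, dark genes |
| `lne.survival` | self-contained Kaplan–Meier estimation and two-group log-rank test |
| `lne.synthetic` | simulator that plants a DNB module (rising intra-module correlation and variance, falling outside correlation) at a chosen critical stage, with linked survival |
| `lne.cli` | `lne` command-line pipeline |

Conventions worth knowing (all documented in the module docstrings):
natural logarithm in the entropy; zero-variance genes get Pearson
correlation 0; an all-zero weight vector falls back to uniform; sample
(n−1) standard deviations; neighbor order is lexicographic; edge
scores can be on the unit or STRING 0–1000 scale (`0.800` ⇔ `800`).
Inputs are assumed pre-mapped to gene symbols.

## CLI

Generate a synthetic study and run the full pipeline on it:

```sh
lne simulate --out demo --seed 1
lne full \
  --expression demo/expression.tsv --network demo/network.tsv \
  --annotations demo/annotations.tsv --clinical demo/clinical.tsv \
  --stage-order I,II,III,IV --out demo/results
```

Outputs: `scores.tsv` (sample, stage, global score), per-sample
`profiles/*.tsv` (gene, E_ref, E_mixed, dE, dSD, dE×dSD, rank),
`stage_curve.tsv`, `transition.tsv` (called stage plus before/after
log-rank), `dnb_genes.txt` and the induced `dnb_subnetwork.sif`/
`.graphml` (Cytoscape-readable, with mean local score per node and
|PCC| per edge), `biomarkers.tsv`, `dark_genes.txt`, and a JSON run
manifest. `lne score` / `lne transition` / `lne biomarkers` run the
stages individually; every flag can also be given via `--config
config.yaml` (flags win). All randomness flows from the single seed;
identical configs give byte-identical outputs.

Real-data inputs follow the same formats: a genes × samples
tab/comma-delimited expression matrix, an edge list
(`protein1 protein2 combined_score`, e.g. STRING with
`--score-scale string-1000 --threshold 0.8`), a sample annotation
table (`sample_id`, `group` = reference/case, `stage`), and optionally
a clinical table (`sample_id`, `time`, `event`).

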