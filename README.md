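# metnetkit

A library and CLI for metabolic-network analysis of multi-omics fly
studies:

- **pathway_db** — a compound / reaction / enzyme / gene / pathway
  database with a native five-table TSV dialect, a reader for a subset
  of BioCyc-style attribute-value `.dat` files, referential-integrity
  validation, and identifier resolution (id > name > synonym > xref).
- **network_builder** — the four graph types derived from a reaction
  set: compound (C), compound–reaction (CR), compound–gene (CG), and
  compound–reaction–enzyme–gene (CREG), plus seed-list expansion,
  pathway queries, CREG→CG contraction, and subnetwork extraction.
- **omics_overlay** — attaches differential metabolomics /
  transcriptomics results to network nodes and derives categorical
  visual attributes (hexagon/circle/square/diamond shapes, measured vs
  unmeasured fills, |log2FC|-scaled sizes, significance outlines).
- **enrichment** — exact upper-tail hypergeometric over-representation
  of compound sets against pathway definitions with Benjamini–Hochberg
  FDR, and PCA-loading top/bottom-quartile selection.
- **metabolomics_stats** — the differential-abundance pipeline:
  per-condition 50 %-missing filtering, half-minimum imputation, range
  scaling, Welch's t-test and one-way ANOVA with BH FDR, RSD QC, PCA
  with 95 % group ellipses, Ward/Euclidean clustering, and fold-change
  distribution summaries.
- **flic_events** — feeding analytics for 5 Hz interaction signals:
  threshold detection, run-length event detection with end-of-recording
  censoring, per-fly summaries, device-stratified BCa bootstrap of the
  median, and a stratified randomization test on median differences.
- **synthetic** — deterministic generators: toy pathway databases,
  log-normal omics tables with planted fold changes and missingness,
  and two-state feeding traces with known bout ground truth.
- **io / cli** — GraphML / SIF / CX-JSON / edge-TSV graph export
  (deterministic, GraphML round-trips byte-identically), omics-table
  reading/writing, YAML run configuration, and the `metnetkit` CLI.

## CLI

```sh
metnetkit db validate path/to/db
metnetkit network build path/to/db --pathway PW_TCA --graph-type CREG --out net.graphml
metnetkit network subnet path/to/db --source-pathway PW_TCA --keep C_MAL,C_FUM,R_FUM --out sub.graphml
metnetkit overlay path/to/db --pathway PW_TCA --compound-results de.tsv --out styled.graphml
metnetkit enrich sets.gmt --selected sel.txt --universe uni.txt --out enr.tsv
metnetkit stats run omics.csv conditions.tsv --group-a CD_fasted --group-b CD_refed --out de.tsv
metnetkit flic traces.csv --out summaries.tsv
metnetkit simulate --what omics --seed 7 --n-features 100 --planted 30 --out-dir sim/
```

Exit codes: 0 ok, 1 data error, 2 usage error.

### Native database dialect

Five UTF-8 TSV tables with mandatory headers; list cells are
pipe-delimited, xrefs are `namespace:value` pairs:

| file | columns |
|---|---|
| `compounds.tsv` | id, name, synonyms, xrefs, class_label |
| `reactions.tsv` | id, substrates, products, reversible, enzymes, pathways |
| `enzymes.tsv` | id, name, genes, reactions |
| `genes.tsv` | id, symbol, enzymes |
| `pathways.tsv` | id, name, compounds, reactions |

### Omics table format

Features as rows, first column the feature id, header row the sample
ids; empty cells or `NA` are missing values.  A two-column TSV sidecar
(`sample`, `condition`) assigns each sample its condition label.

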