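# quantdea

Differential expression analysis (DEA) for quantitative proteomics, as a
scriptable command-line pipeline. `quantdea` starts from the tabular outputs
of protein quantification software — DIA-NN (`report.tsv`), FragPipe TMT
(`psm.tsv`), MaxQuant (`peptides.txt`) — and produces per-protein fold
changes, moderated test statistics and a complete, replicable result folder.
It is aimed at proteomics core facilities and analysts who need to queue many
DEA jobs non-interactively (e.g. from a workflow manager or LIMS), not at
interactive point-and-click exploration.

## What it computes

**Ingestion with identification filters.** Each reader converts its dialect
into one tidy (sample, protein, peptide, intensity) table, applying the
recommended confidence filters on the way in: DIA-NN rows with protein-group
q-value > 0.01 are removed; FragPipe TMT PSMs require isolation purity ≥ 0.5
and PeptideProphet probability > 0.9; MaxQuant reverse and contaminant rows
are dropped. Zero and blank intensities both mean "not observed". Custom
parsers can be injected through a reader registry.

**Protein metadata from the FASTA.** Sequence length, gene name (`GN=` tag)
and the number of theoretically observable tryptic peptides (fully tryptic,
cleavage after K/R except before P, 6–30 residues) are derived directly from
the search database, and iBAQ values are computed as

    iBAQ = (summed peptide intensity) / (number of theoretical tryptic peptides).

**Normalization and summarization.** Intensities are log2-transformed and
robustly scaled per sample (median/MAD); each protein's peptide × sample
matrix is then summarized by Tukey's median polish,
`y_ij = m + peptide_i + sample_j + e_ij`, with the protein abundance in
sample *j* taken as `m + sample_j`.

**Design and contrasts.** The experimental design lives in one annotation
table (sample id, name, group, optional subject, and either a `control`
column or explicit `ContrastName`/`Contrast` columns). Contrasts are
arithmetic expressions over `G_`-prefixed group means, e.g.

    (G_T_Old + G_T_Young)/2 - (G_NAT_Old + G_NAT_Young)/2

and may reference previously defined contrasts (differences of differences,
i.e. interactions). Expressions compile to linear coefficient vectors over
the group means.

**Moderated statistics.** Per protein, abundances are regressed on group
indicators (plus subject fixed effects for paired designs). Residual
variances are shrunk toward the ensemble mean with a prior worth `prior_df`
degrees of freedom; contrasts are tested with a t distribution on
`df + prior_df` degrees of freedom, and p-values are Benjamini–Hochberg
adjusted within each contrast. Proteins with a contrast group entirely
unobserved are never dropped: they are reported without fold change and
p-value, or with a detection-limit fold change flagged `imputed_fc`.

## Worked example

Generate a synthetic two-group experiment with known ground truth (120
proteins, 3 vs 3, 10% regulated at |log2FC| = 1), then run the full DEA:

```sh
quantdea simulate --out sim/ --seed 11 --params <(echo "n_proteins: 120
n_per_group: 3")
quantdea dea -i sim/ -d sim/annotation.tsv -s DIANN -o result/
```

which prints

```
DEA result folder written to result/
```

and produces `result/inputs/` (annotation, parameters, invocation record)
plus `result/results/` with `DE_analysis.xlsx` (+ TSV mirrors),
`IBAQ_analysis.xlsx`, `GSEA_trt_vs_ctrl.rnk`, `ORA_trt_vs_ctrl.txt`,
`ORA_background.txt`, `experiment_bundle/`, `DE_analysis.html` and
`QC_analysis.html`. The first lines of the rank file (gene identifier,
t-statistic, sorted descending — the input format for GSEA tools):

```
GENE00115	5.46889943
GENE00095	4.577176701
GENE00067	4.567654337
```

Here GENE00115 is one of the simulated up-regulated proteins: its moderated
t-statistic of 5.47 corresponds to an estimated log2 fold change of 1.08
(true value 1) with BH-adjusted p = 0.0049, so it clears the default
significance thresholds and appears in `ORA_trt_vs_ctrl.txt`.
Re-running `quantdea dea` on the copied `inputs/` reproduces `results/`
byte-for-byte.

The other entry points mirror the same workflow: `quantdea dataset` extracts
sample names from a report into an annotation template, `quantdea yaml`
writes the default parameter file, and `quantdea qc` produces the
quality-control tables (CV and missingness per group, peptides per protein,
sample-size estimation) without fitting models.

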