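# Methods

This note documents the statistical model behind `quantdea`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Data model and ingestion

All stages exchange a single long-format table of
(sample, protein, peptide, intensity) observations with a column-role
configuration. Two conventions are applied at ingestion and never
revisited:

* **Zero means missing.** Quantification tools use `0` and blank
  interchangeably for "not observed"; both are converted to missing (the
  row is dropped) and missingness is re-derived per group later. Retained
  intensities are therefore strictly positive before the log transform.
* **One aggregation policy per stage.** DIA-NN charge states of the same
  stripped peptide collapse to the maximum intensity per sample at read
  time; TMT PSMs of the same peptide are summed per channel (PSM counts are
  additive evidence); peptide-to-protein aggregation happens only in the
  summarization stage.

Filter thresholds follow the conventions of the upstream tools: DIA-NN
protein-group q-value ≤ 0.01 (boundary retained), TMT purity ≥ 0.5
(boundary retained), PeptideProphet probability > 0.9 (boundary excluded).
All are YAML-configurable (`filters:`). The DIA-NN precursor-level q-value
is not filtered by default; a config slot (`diann_precursor_qvalue`) exists
for it. Exact dialect column names live in one declarative map per reader,
since upstream tools rename columns between versions.

## Normalization

`normalization.method` ∈ {`robscale` (default), `quantile`, `none`}.

`robscale` log2-transforms and then, per sample *s*,

    y' = (y − median_s) / MAD_s × mean(MAD over samples) + grand median,

removing per-sample loading (median) and scale (MAD) differences while
keeping values in interpretable log2 units (every sample's median equals
the grand median afterwards). MAD uses the normal-consistency factor.
Samples with fewer than three observed values, or zero MAD, are left
log2-only with a warning. Variance-stabilizing normalization (an
affine-glog maximum-likelihood fit) is a different method family and is
deliberately not offered; `robscale` is this package's default and the
report header records the method used. Quantile normalization maps each
observed value to the mean of the per-sample quantile functions on a
101-point grid.

Normalization is monotone within each sample by construction, a property
the test suite asserts.

## Peptide-to-protein summarization: Tukey median polish

For each protein, the peptide × sample matrix of normalized log2
intensities is decomposed as

    y_ij = m + r_i + c_j + e_ij

by alternating row- and column-median sweeps (rows first — the classical
order), stopping when the change in Σ|e| drops below `tol` (default 1e-6)
or after `max_iter` (default 10) iterations. The decomposition identity
`m + r_i + c_j + e_ij = y_ij` holds exactly at every observed cell at every
iteration, because sweeps only move mass between components. The protein
abundance in sample *j* is `m + c_j`, reported only for samples with at
least one observed peptide. Median-based summarization is robust to a
single interfering or mis-assigned peptide, which distinguishes it from
sum- or mean-based rollups.

The inner median uses a sort-based NaN-aware routine equivalent to
`numpy.nanmedian` (even counts average the two central order statistics);
the test suite checks the whole decomposition against an independently
coded pure-Python polish at 1e-10 on randomly missing matrices.

## Per-protein model and moderated contrasts

Protein abundances are regressed on group indicators with cell-means
coding (no intercept), plus subject indicator columns (first observed
subject as reference) when the annotation has a `subject` column. Subject
blocking uses fixed effects: deterministic, dependency-light, and exact for
the balanced paired designs it is meant for; contrasts whose coefficients
sum to zero are invariant to the reference-subject choice. Estimability
under singular designs (e.g. a subject fully confounded with a group) is
checked by projecting the contrast onto the row space of the design; a
non-estimable contrast is flagged rather than silently reported.

Residual variances are moderated by shrinking toward the ensemble mean:

    s²_i,shrunk = (d0·s0² + df_i·s²_i) / (d0 + df_i),   df_i,eff = df_i + d0

with `s0² = mean(s²)` over proteins with at least one residual degree of
freedom and `d0 = processing.prior_df` (default 10; 0 disables moderation
and recovers the classical per-protein t-test exactly — the suite verifies
equality with a pooled two-sample t-test at 1e-10). The moment-based prior
is intentionally simple; the default of 10 extra degrees of freedom gives
near-nominal type-I error on 3 vs 3 null simulations (asserted in the
acceptance tests as a band of [0.03, 0.07] at nominal 0.05) while
stabilizing small-sample variances.

A contrast `c` is estimated as `Σ c_g·mean_g` with standard error
`sqrt(s²_shrunk · cᵀ(XᵀX)⁺c)` and a two-sided p-value from the t
distribution on the effective degrees of freedom.

### Missingness policy

Proteins are never removed for having missing values. "Excess missingness"
is operationalized as the unambiguous case: a contrast-relevant group with
*zero* observations (partially observed groups are always modelled). Then:

* `processing.missing_strategy: omit` — the protein is reported with empty
  fold-change and p-value cells (`not_estimable`), but stays in every
  output table;
* `model` (default) — the missing group's mean is set to the dataset-wide
  detection limit (the `detection_quantile` = 0.05 quantile of all observed
  log2 abundances) so a fold-change direction and magnitude can be
  reported, flagged `imputed_fc`. No p-value accompanies an imputed fold
  change: it has no sampling-variance basis.

This is narrower than a full missingness model (no partial-information
likelihood); it trades some power on borderline proteins for an unambiguous
and easily audited rule.

### FDR

Benjamini–Hochberg adjustment is applied within each contrast separately
(contrasts answer different questions; pooling them would couple their
discovery lists). BH depends on the p-value *distribution*, not the number
of tests: duplicating the p-vector leaves every adjusted value unchanged,
and removing a random half of the proteins changes the discovery
proportion only within sampling noise — both are asserted as tests, which
is why post-hoc filtering (e.g. by peptides-per-protein, using the QC
columns in the output workbook) does not invalidate the FDR of what
remains.

## QC statistics and sample-size estimation

Per (protein, group): observed/missing counts and the coefficient of
variation computed on linear-scale intensities (back-transformed from log2
when needed), left empty below two observations. Per protein: peptide
counts per sample and over the experiment. The sample-size table uses the
standard two-sample normal approximation

    n = ceil( 2σ²(z₁₋α/2 + z_power)² / δ² ),  minimum 2,

evaluated at the 50th/75th/90th percentiles of the empirical within-group
standard deviation distribution (log2 scale) and δ ∈ {0.5, 1, 2}, with
α = 0.05 and power 0.8. It is a planning heuristic, not a test.

## Synthetic data generator

`quantdea.simulate` writes the on-disk dialects the readers parse (a
DIA-NN-style `report.tsv`, a UniProt-style FASTA, an annotation table, and
for TMT a `psm.tsv`), so every end-to-end test also exercises the parsers.
The generative model: protein baselines N(20, 2²) on log2 scale (typical
DIA precursor intensities), peptide offsets N(0, 1), geometric
peptides-per-protein (mean 4, minimum 1), a fixed ±`log2fc_effect` added to
non-reference groups for a `frac_regulated` subset, within-group noise
N(0, `sigma_within`), and logistic missing-at-low-abundance dropout with
its midpoint at the 10th abundance percentile and slope −1 per log2 unit —
low-abundance observations drop out preferentially, as in real DIA data.
Default study conditions for calibration experiments are 2000 proteins and
5 (recovery) or 3 (null calibration) replicates per group with
`sigma_within` 0.3.

What it does **not** emulate: correlated peptides within a protein beyond
the additive offset, shared peptides between proteins, retention-time or
mass-error structure, interference/ratio compression in TMT, batch
effects, or heavy-tailed error distributions. Passing calibration tests on
this generator therefore demonstrates the statistical machinery is correct
under its stated assumptions, not that real data meet those assumptions.

## Output contract and determinism

A DEA run writes `inputs/` (annotation, YAML, invocation record) and
`results/` (DE and iBAQ workbooks with TSV mirrors, per-contrast `.rnk`
rank files sorted by t-statistic, ORA lists plus background, a portable
experiment bundle with a JSON manifest, and static HTML reports). Rank
files exclude rows without a t-statistic and collapse duplicate gene
identifiers to the entry with the largest |t|. All stages are
deterministic, XLSX metadata timestamps are pinned, and figures embed as
base64 PNGs, so re-running on the copied `inputs/` reproduces `results/`
byte-identically — asserted end-to-end in the test suite. An optional
`scripts/bundle_to_se.R` converts the bundle into a SummarizedExperiment
`.rds` for downstream R viewers; it performs format conversion only.

## Numerical conventions and edge cases

* Group keys are case-sensitive; sample-id matching (exact first, then
  basename without final extension) is the only normalization point, and
  ambiguity there is fatal rather than guessed.
* Contrast expressions use standard precedence; division is only by
  numeric literals (keeps linearity decidable); a contrast may reference
  only contrasts defined on earlier rows — forward references are
  rejected, keeping compilation a single pass with order-independent
  semantics per row.
* Control-column designs name contrasts `<group>_vs_<control>`.
* σ² = 0 with `prior_df` 0 yields a fold change with no p-value (zero
  variance is not evidence).
* Proteins present in the data but absent from the FASTA get empty
  metadata fields and a warning, never an error.
* Test and acceptance problem sizes (200 random matrices, 500 oracle
  proteins/sequences, 2000-protein simulations, 10–20 null replicates)
  were chosen to make sampling error small relative to the asserted
  tolerances while keeping a full run to a few minutes on one CPU.

## Known limitations

No protein-group inference or razor-peptide reassignment (the
quantification software's grouping is taken as given); no mixed-effects or
count-based models; no peptide-level fold changes alongside protein-level
results; Spectronaut and FragPipe-DDA msstats readers are registry slots
without built-in parsers; the HTML report is static (no linked
brushing/interactivity).
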