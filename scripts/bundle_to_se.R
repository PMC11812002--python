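#!/usr/bin/env Rscript
# Convert a quantdea experiment bundle into a SummarizedExperiment .rds.
# Pure format conversion; no computation.
#
#   Rscript scripts/bundle_to_se.R <bundle_dir> <out.rds>

suppressMessages({
  library(SummarizedExperiment)
  library(jsonlite)
  library(yaml)
})

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 2) stop("usage: bundle_to_se.R <bundle_dir> <out.rds>")
bundle_dir <- args[1]
out_rds <- args[2]

manifest <- fromJSON(file.path(bundle_dir, "manifest.json"))
if (!identical(manifest$format_version, "1.0")) {
  stop("unsupported bundle format version: ", manifest$format_version)
}

assay <- as.matrix(read.delim(file.path(bundle_dir, manifest$files$assay),
                              row.names = 1, check.names = FALSE))
row_meta <- read.delim(file.path(bundle_dir, manifest$files$row_metadata),
                       row.names = 1, check.names = FALSE)
col_meta <- read.delim(file.path(bundle_dir, manifest$files$col_metadata),
                       row.names = 1, check.names = FALSE)
params <- yaml.load_file(file.path(bundle_dir, manifest$files$parameters))

stopifnot(nrow(assay) == nrow(row_meta), ncol(assay) == nrow(col_meta))

se <- SummarizedExperiment(
  assays = list(abundance = assay),
  rowData = row_meta[rownames(assay), , drop = FALSE],
  colData = col_meta[colnames(assay), , drop = FALSE],
  metadata = list(parameters = params, manifest = manifest)
)
saveRDS(se, out_rds)
cat(sprintf("wrote %s: %d proteins x %d samples\n", out_rds, nrow(se), ncol(se)))
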