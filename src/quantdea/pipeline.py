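"""End-to-end QC and DEA pipelines gluing the stage modules together.

These functions are what the command-line entry points call; they are plain
functions so workflow managers (or tests) can drive them directly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import dea as dea_mod
from . import fastainfo, outputs, preprocess, readers
from .config import reader_filter_kwargs
from .model import TidyQuantTable, restrict_to_annotation, validate_table

logger = logging.getLogger(__name__)


def setup_run_logging(log_path: Path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("quantdea")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def _find_fasta(input_dir: Path, explicit: str | Path | None) -> Path | None:
    if explicit:
        return Path(explicit)
    hits = sorted(input_dir.glob("*.fasta")) + sorted(input_dir.glob("*.fasta.gz"))
    return hits[0] if hits else None


def load_and_prepare(
    input_dir: str | Path,
    annotation_path: str | Path,
    software: str,
    config: dict,
):
    """Shared ingestion: parse, match samples, validate, normalize, summarize."""
    input_dir = Path(input_dir)
    spec = readers.get_reader(software)
    logger.info("reading %s input from %s", software, input_dir)
    table = readers.read_quant_table(input_dir, software,
                                     **reader_filter_kwargs(config, software))
    logger.info("parsed %d observations, %d samples, %d proteins",
                len(table), len(table.samples), len(table.proteins))

    annotation = ann_mod.parse_annotation(annotation_path)
    mapping = ann_mod.match_sample_ids(annotation.sample_ids, table.samples)
    annotation = annotation.rename_samples(mapping)
    report = validate_table(table, annotation)
    if report.samples_only_in_data:
        logger.warning("dropping unannotated samples: %s", report.samples_only_in_data)
    table = restrict_to_annotation(table, annotation)

    contrasts = ann_mod.compile_contrasts(annotation)
    logger.info("design: groups=%s contrasts=%s", annotation.groups, contrasts.names())

    fasta_path = _find_fasta(input_dir, config.get("fasta", {}).get("path"))
    infos = None
    ibaq = None
    if fasta_path is not None:
        fa = config.get("fasta", {})
        infos = fastainfo.parse_fasta_info(
            fasta_path,
            min_len=fa.get("min_peptide_length", fastainfo.MIN_PEPTIDE_LENGTH),
            max_len=fa.get("max_peptide_length", fastainfo.MAX_PEPTIDE_LENGTH),
        )
        ibaq = fastainfo.ibaq_table(table, infos, annotation)
        logger.info("FASTA: %d proteins with metadata", len(infos))

    method = config.get("normalization", {}).get("method", "robscale")
    norm = preprocess.log2_and_normalize(table, method=method)
    logger.info("normalization: %s", method)

    if spec.level == "peptide":
        # peptide-centric analysis: the peptide is the modeling unit
        r = norm.roles
        df = norm.data.copy()
        df[r.protein_id] = df[r.protein_id].astype(str) + "~" + df[r.peptide_id].astype(str)
        unit_table = TidyQuantTable(df, r)
        protein_table = preprocess.summarize_proteins(unit_table)
    else:
        protein_table = preprocess.summarize_proteins(norm)
    logger.info("summarized to %d (unit, sample) abundances", len(protein_table))

    qc = preprocess.qc_statistics(norm, annotation, protein_table)
    protein_info = (
        fastainfo.protein_info_frame(infos, list(protein_table.proteins))
        if infos is not None else None
    )
    return {
        "table": table, "norm": norm, "protein_table": protein_table,
        "annotation": annotation, "contrasts": contrasts, "qc": qc,
        "protein_info": protein_info, "ibaq": ibaq, "fasta": fasta_path,
        "level": spec.level,
    }


def run_qc_pipeline(
    input_dir: str | Path,
    annotation_path: str | Path,
    software: str,
    config: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """QC application: abundance/iBAQ workbook, QC statistics, sample-size report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = setup_run_logging(out_dir / "qc.log")
    try:
        prep = load_and_prepare(input_dir, annotation_path, software, config)
        protein_table = prep["protein_table"]
        qc = prep["qc"]
        annotation = prep["annotation"]

        abundance = protein_table.data.pivot_table(
            index=protein_table.roles.protein_id,
            columns=protein_table.roles.sample_id,
            values=protein_table.roles.intensity,
            aggfunc="first", observed=True,
        ).sort_index()
        sheets = {
            "protein_abundance_log2": abundance.reset_index(),
            "qc_group_stats": qc.group_stats,
            "peptides_per_protein": qc.peptides_per_protein,
            "peptides_per_sample": qc.peptides_per_sample.reset_index(),
        }
        if prep["ibaq"] is not None:
            sheets["ibaq"] = prep["ibaq"].reset_index()
        paths = {"xlsx": outputs.write_xlsx(sheets, out_dir / "proteinAbundances.xlsx")}

        sds = preprocess.within_group_sds(protein_table, annotation)
        size_table = preprocess.sample_size_estimate(sds)
        paths["sample_size_tsv"] = out_dir / "QC_sampleSizeEstimation.tsv"
        size_table.to_csv(paths["sample_size_tsv"], sep="\t", index=False)
        paths["sample_size_html"] = _write_simple_html(
            out_dir / "QC_sampleSizeEstimation.html",
            "QC and sample-size estimation",
            {
                "Required replicates per group": size_table,
                "Per-group protein statistics (head)": qc.group_stats.head(50),
            },
        )
        counts = abundance.notna().sum(axis=0).rename("proteins").reset_index()
        counts.columns = ["sample", "proteins"]
        paths["abundance_html"] = _write_simple_html(
            out_dir / "QC_proteinAbundance.html",
            "Protein abundance overview",
            {"Proteins quantified per sample": counts},
        )
        logger.info("QC outputs written to %s", out_dir)
        return paths
    finally:
        logging.getLogger("quantdea").removeHandler(handler)
        handler.close()


def _write_simple_html(path: Path, title: str, tables: dict[str, pd.DataFrame]) -> Path:
    body = "".join(
        f"<h2>{name}</h2>" + df.to_html(index=False, border=0,
                                        float_format=lambda v: f"{v:.4g}")
        for name, df in tables.items()
    )
    path.write_text(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{title}</title></head><body><h1>{title}</h1>{body}</body></html>"
    )
    return path


def run_dea_pipeline(
    input_dir: str | Path,
    annotation_path: str | Path,
    software: str,
    config: dict,
    out_dir: str | Path,
    yaml_path: str | Path | None = None,
    name: str = "analysis",
) -> Path:
    """DEA application: the full ResultFolder (inputs/ + results/)."""
    out_root = Path(out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    handler = setup_run_logging(out_root / "dea.log")
    try:
        config = dict(config)
        config["software"] = software
        prep = load_and_prepare(input_dir, annotation_path, software, config)
        proc = config.get("processing", {})
        result = dea_mod.run_dea(
            prep["protein_table"],
            prep["annotation"],
            prep["contrasts"],
            prior_df=float(proc.get("prior_df", dea_mod.PRIOR_DF_DEFAULT)),
            missing_strategy=proc.get("missing_strategy", "model"),
            detection_quantile=float(proc.get("detection_quantile", 0.05)),
            qc=prep["qc"],
            protein_info=prep["protein_info"],
            config=config,
        )
        logger.info("DEA: %d proteins x %d contrasts tested",
                    result.abundance.shape[0], len(result.contrasts))

        results_dir = out_root / "results"
        results_dir.mkdir(parents=True, exist_ok=True)
        thr = config.get("thresholds", {})
        fdr_thr = float(thr.get("fdr", 0.05))
        fc_thr = float(thr.get("log2fc", 1.0))

        outputs.write_dea_tables(result, results_dir, name=name, ibaq=prep["ibaq"])
        for contrast in result.contrasts.names():
            outputs.write_rnk(result, contrast, results_dir / f"GSEA_{contrast}.rnk")
        outputs.write_ora_lists(result, fdr_thr, fc_thr, results_dir)
        outputs.write_experiment_bundle(result, results_dir / "experiment_bundle")
        outputs.render_report(result, results_dir / f"DE_{name}.html",
                              fdr_thr=fdr_thr, fc_thr=fc_thr, peptide_table=prep["norm"])
        _write_dea_qc_html(result, results_dir / f"QC_{name}.html")

        outputs.copy_inputs(
            out_root,
            {"annotation": Path(annotation_path),
             "yaml": Path(yaml_path) if yaml_path else None},
            invocation={
                "software": software,
                "input_dir": str(Path(input_dir).name),
                "annotation": Path(annotation_path).name,
                "yaml": Path(yaml_path).name if yaml_path else None,
                "config": _jsonable(config),
                "name": name,
            },
        )
        logger.info("result folder complete: %s", out_root)
        return out_root
    finally:
        logging.getLogger("quantdea").removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_dea_qc_html(result, path: Path) -> Path:
    """Secondary QC document: p-value histograms and missingness per contrast."""
    import base64

    from .outputs import _p_hist  # noqa: PLC2701 - same package

    sections = []
    for name in result.contrasts.names():
        sub = result.contrast_stats(name)
        sections.append(
            f"<h2>{name}</h2>"
            f'<img src="data:image/png;base64,{_p_hist(sub, name)}"/>'
        )
    status_counts = (
        result.stats.groupby(["contrast", "status"], observed=True).size()
        .rename("n").reset_index()
    )
    sections.append(
        "<h2>Estimation status per contrast</h2>"
        + status_counts.to_html(index=False, border=0)
    )
    path.write_text(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>DEA quality control</title></head><body>"
        "<h1>DEA quality control</h1>" + "".join(sections) + "</body></html>"
    )
    return path
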