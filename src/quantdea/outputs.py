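"""The result contract: workbooks, rank files, ORA lists, bundle, HTML report.

Every DEA run emits a self-contained folder:

    <out>/
      inputs/    annotation, YAML parameters, invocation record
      results/   DE_<name>.xlsx (+ TSV mirrors), IBAQ_<name>.xlsx,
                 GSEA_<contrast>.rnk, ORA_<contrast>.txt, ORA_background.txt,
                 experiment_bundle/, DE_report.html, QC tables

Re-running the pipeline on the copied ``inputs/`` reproduces ``results/``
byte-identically: all stages are deterministic and the XLSX writer below
pins the workbook timestamps.
"""

from __future__ import annotations

import base64
import datetime
import io
import json
import logging
import re
import shutil
import zipfile
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .dea import DEAResult, STATUS_MODELLED

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = "1.0"
_FIXED_TIMESTAMP = datetime.datetime(2000, 1, 1)
_FIXED_ZIP_DATE = (2000, 1, 1, 0, 0, 0)


# ---------------------------------------------------------------------------
# deterministic XLSX writing


def write_xlsx(sheets: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Write a multi-sheet workbook with pinned timestamps (byte-deterministic)."""
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, df in sheets.items():
            df.to_excel(writer, sheet_name=name[:31], index=False)
        props = writer.book.properties
        props.created = _FIXED_TIMESTAMP
        props.modified = _FIXED_TIMESTAMP
    _fix_zip_timestamps(path)
    return path


_CORE_TS = re.compile(
    rb'(<dcterms:(?:created|modified)[^>]*>)[^<]*(</dcterms:(?:created|modified)>)'
)


def _fix_zip_timestamps(path: Path) -> None:
    # openpyxl stamps wall-clock times into docProps/core.xml and the zip
    # directory at save time; pin both so identical inputs give identical bytes
    with zipfile.ZipFile(path) as zin:
        entries = [(info.filename, zin.read(info.filename)) for info in zin.infolist()]
    entries.sort(key=lambda e: e[0])
    fixed = _FIXED_TIMESTAMP.strftime("%Y-%m-%dT%H:%M:%SZ").encode()
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zout:
        for name, data in entries:
            if name == "docProps/core.xml":
                data = _CORE_TS.sub(rb"\g<1>" + fixed + rb"\g<2>", data)
            info = zipfile.ZipInfo(name, date_time=_FIXED_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zout.writestr(info, data)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# DE / iBAQ tables


def write_dea_tables(result: DEAResult, out_dir: str | Path, name: str = "analysis",
                     ibaq: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write DE_<name>.xlsx (+ TSV mirrors) and IBAQ_<name>.xlsx."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stats = result.stats.copy()
    if result.protein_info is not None:
        stats = stats.merge(result.protein_info, on="protein_id", how="left")
    abundance = result.abundance.reset_index()
    sheets = {
        "diff_expression": stats,
        "protein_abundance": abundance,
        "group_means": result.group_means.reset_index(),
        "annotation": result.annotation.table,
    }
    if result.qc is not None:
        sheets["qc_group_stats"] = result.qc.group_stats
        sheets["qc_peptides_per_protein"] = result.qc.peptides_per_protein
        sheets["qc_peptides_per_sample"] = result.qc.peptides_per_sample.reset_index()
    paths = {"de_xlsx": write_xlsx(sheets, out_dir / f"DE_{name}.xlsx")}
    paths["de_stats_tsv"] = _write_tsv(stats, out_dir / f"DE_{name}_stats.tsv")
    paths["abundance_tsv"] = _write_tsv(abundance, out_dir / f"DE_{name}_abundance.tsv")
    if result.qc is not None:
        paths["qc_tsv"] = _write_tsv(result.qc.group_stats, out_dir / f"DE_{name}_qc.tsv")

    if ibaq is not None:
        ib = ibaq.reset_index()
        paths["ibaq_xlsx"] = write_xlsx({"ibaq": ib}, out_dir / f"IBAQ_{name}.xlsx")
        paths["ibaq_tsv"] = _write_tsv(ib, out_dir / f"IBAQ_{name}.tsv")
    return paths


# ---------------------------------------------------------------------------
# GSEA rank files and ORA lists


def _identifier_map(result: DEAResult) -> pd.Series:
    """Gene name when the FASTA provided one, else the protein id."""
    if result.protein_info is None:
        ids = pd.Series(dtype=object)
    else:
        pi = result.protein_info.set_index("protein_id")
        ids = pi["gene_name"] if "gene_name" in pi.columns else pd.Series(dtype=object)
    proteins = pd.unique(result.stats["protein_id"])
    return pd.Series(
        {p: (ids.get(p) if pd.notna(ids.get(p, np.nan)) and ids.get(p) else p)
         for p in proteins}
    )


def write_rnk(result: DEAResult, contrast: str, path: str | Path) -> Path:
    """Two-column headerless rank file: identifier, t-statistic, sorted descending.

    Rows without a t-statistic (not estimable or imputed fold changes) are
    excluded; duplicate identifiers keep the entry with the largest |t|.
    """
    sub = result.contrast_stats(contrast)
    if sub.empty:
        raise KeyError(f"unknown contrast {contrast!r}")
    sub = sub.dropna(subset=["t"]).copy()
    idmap = _identifier_map(result)
    sub["identifier"] = sub["protein_id"].map(idmap)
    before = len(sub)
    sub = sub.loc[sub.groupby("identifier")["t"].transform(lambda v: v.abs() == v.abs().max())]
    sub = sub.drop_duplicates(subset="identifier", keep="first")
    if len(sub) < before:
        logger.warning("rnk %s: %d duplicate identifiers collapsed (kept max |t|)",
                       contrast, before - len(sub))
    sub = sub.sort_values(["t", "identifier"], ascending=[False, True])
    path = Path(path)
    with open(path, "w") as fh:
        for ident, t in zip(sub["identifier"], sub["t"]):
            fh.write(f"{ident}\t{t:.10g}\n")
    return path


def write_ora_lists(result: DEAResult, fdr_thr: float, fc_thr: float,
                    out_dir: str | Path) -> dict[str, Path]:
    """Per-contrast significant-identifier lists plus one background file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idmap = _identifier_map(result)
    paths: dict[str, Path] = {}
    background: list[str] = []
    for name in result.contrasts.names():
        sub = result.contrast_stats(name)
        sig = sub[(sub["p_adj"] <= fdr_thr) & (sub["log2fc"].abs() >= fc_thr)]
        idents = sorted(set(sig["protein_id"].map(idmap)))
        p = out_dir / f"ORA_{name}.txt"
        p.write_text("".join(f"{i}\n" for i in idents))
        paths[name] = p
        background.extend(sub.loc[sub["status"] == STATUS_MODELLED, "protein_id"].map(idmap))
    bg = out_dir / "ORA_background.txt"
    bg.write_text("".join(f"{i}\n" for i in sorted(set(background))))
    paths["background"] = bg
    return paths


# ---------------------------------------------------------------------------
# experiment bundle


def write_experiment_bundle(result: DEAResult, out_dir: str | Path) -> Path:
    """Serialize assays + row/col metadata + parameters as a portable bundle.

    The bundle is sufficient to construct a SummarizedExperiment (or an
    AnnData) downstream without recomputation; ``manifest.json`` records the
    format version and the key analysis parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    abundance = result.abundance
    _write_tsv(abundance, out_dir / "abundance.tsv", index=True)

    row_meta = result.group_means.copy()
    if result.protein_info is not None:
        row_meta = row_meta.join(result.protein_info.set_index("protein_id"), how="left")
    stats_wide = result.stats.pivot(
        index="protein_id", columns="contrast",
        values=["log2fc", "t", "p", "p_adj", "status"],
    )
    stats_wide.columns = [f"{v}.{c}" for v, c in stats_wide.columns]
    row_meta = row_meta.join(stats_wide, how="left").loc[abundance.index]
    _write_tsv(row_meta, out_dir / "row_metadata.tsv", index=True)

    col_meta = result.annotation.table.set_index("sample_id").loc[list(abundance.columns)]
    _write_tsv(col_meta, out_dir / "col_metadata.tsv", index=True)

    with open(out_dir / "parameters.yaml", "w") as fh:
        yaml.safe_dump(result.config, fh, sort_keys=True)

    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "n_proteins": int(abundance.shape[0]),
        "n_samples": int(abundance.shape[1]),
        "contrasts": result.contrasts.names(),
        "software": result.config.get("software"),
        "normalization": result.config.get("normalization", {}).get("method"),
        "thresholds": result.config.get("thresholds", {}),
        "detection_limit_log2": (
            None if np.isnan(result.detection_limit) else float(result.detection_limit)
        ),
        "files": {
            "assay": "abundance.tsv",
            "row_metadata": "row_metadata.tsv",
            "col_metadata": "col_metadata.tsv",
            "parameters": "parameters.yaml",
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def read_experiment_bundle(bundle_dir: str | Path) -> dict:
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format {manifest.get('format_version')!r}")
    abundance = pd.read_csv(bundle_dir / "abundance.tsv", sep="\t", index_col=0)
    row_meta = pd.read_csv(bundle_dir / "row_metadata.tsv", sep="\t", index_col=0)
    col_meta = pd.read_csv(bundle_dir / "col_metadata.tsv", sep="\t", index_col=0)
    if abundance.shape[0] != row_meta.shape[0] or abundance.shape[1] != col_meta.shape[0]:
        raise ValueError("bundle dimension mismatch between assay and metadata")
    with open(bundle_dir / "parameters.yaml") as fh:
        params = yaml.safe_load(fh)
    return {"manifest": manifest, "abundance": abundance, "row_metadata": row_meta,
            "col_metadata": col_meta, "parameters": params}


# ---------------------------------------------------------------------------
# static HTML report


def _fig_to_base64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, metadata={"Software": "quantdea"})
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _volcano(sub: pd.DataFrame, name: str, fdr_thr: float, fc_thr: float) -> str:
    fig, ax = plt.subplots(figsize=(4.5, 3.6))
    ok = sub.dropna(subset=["log2fc", "p"])
    sig = (ok["p_adj"] <= fdr_thr) & (ok["log2fc"].abs() >= fc_thr)
    ax.scatter(ok.loc[~sig, "log2fc"], -np.log10(ok.loc[~sig, "p"]), s=4, c="grey", alpha=0.5)
    ax.scatter(ok.loc[sig, "log2fc"], -np.log10(ok.loc[sig, "p"]), s=6, c="firebrick")
    for x in (-fc_thr, fc_thr):
        if fc_thr > 0:
            ax.axvline(x, ls="--", lw=0.7, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title(name, fontsize=9)
    fig.tight_layout()
    return _fig_to_base64(fig)


def _p_hist(sub: pd.DataFrame, name: str) -> str:
    fig, ax = plt.subplots(figsize=(4.5, 2.8))
    ax.hist(sub["p"].dropna(), bins=25, range=(0, 1), color="steelblue")
    ax.set_xlabel("p-value")
    ax.set_ylabel("proteins")
    ax.set_title(name, fontsize=9)
    fig.tight_layout()
    return _fig_to_base64(fig)


def _df_to_html(df: pd.DataFrame) -> str:
    return df.to_html(index=False, border=0, float_format=lambda v: f"{v:.4g}")


def intersection_counts(result: DEAResult, fdr_thr: float, fc_thr: float) -> pd.DataFrame:
    """Upset-style table: size of every intersection pattern of significant sets."""
    sets = {}
    for name in result.contrasts.names():
        sub = result.contrast_stats(name)
        sets[name] = set(
            sub.loc[(sub["p_adj"] <= fdr_thr) & (sub["log2fc"].abs() >= fc_thr), "protein_id"]
        )
    names = list(sets)
    all_sig = sorted(set().union(*sets.values())) if sets else []
    patterns: dict[tuple, int] = {}
    for p in all_sig:
        key = tuple(p in sets[n] for n in names)
        patterns[key] = patterns.get(key, 0) + 1
    rows = [
        {**{n: ("yes" if inc else "") for n, inc in zip(names, key)}, "n_proteins": count}
        for key, count in sorted(patterns.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows, columns=[*names, "n_proteins"])


def render_report(result: DEAResult, path: str | Path,
                  fdr_thr: float = 0.05, fc_thr: float = 1.0,
                  peptide_table=None) -> Path:
    """Assemble the static single-file HTML report."""
    path = Path(path)
    sections = []

    # identification summary
    n_per_sample = (
        result.abundance.notna().sum(axis=0).rename("proteins").to_frame().reset_index()
    )
    n_per_sample.columns = ["sample", "proteins"]
    if peptide_table is not None:
        r = peptide_table.roles
        pep_counts = (
            peptide_table.data.groupby(r.sample_id, observed=True)[r.peptide_id]
            .nunique().rename("peptides")
        )
        n_per_sample["peptides"] = n_per_sample["sample"].map(pep_counts).fillna(0).astype(int)
    missing_dist = (
        result.abundance.isna().sum(axis=1).value_counts().sort_index()
        .rename_axis("n_missing_samples").rename("n_proteins").reset_index()
    )
    sections.append(
        "<h2>Identification summary</h2>"
        + _df_to_html(n_per_sample)
        + "<h3>Missing-value distribution (samples missing per protein)</h3>"
        + _df_to_html(missing_dist)
    )

    # per-contrast volcano + p-value histogram + significance summary
    summary_rows = []
    for name in result.contrasts.names():
        sub = result.contrast_stats(name)
        n_sig = int(((sub["p_adj"] <= fdr_thr) & (sub["log2fc"].abs() >= fc_thr)).sum())
        summary_rows.append(
            {"contrast": name, "n_tested": int(sub["p"].notna().sum()),
             "n_significant": n_sig,
             "n_not_estimable": int((sub["status"] != STATUS_MODELLED).sum())}
        )
        sections.append(
            f"<h2>Contrast: {name}</h2>"
            f'<img src="data:image/png;base64,{_volcano(sub, name, fdr_thr, fc_thr)}"/>'
            f'<img src="data:image/png;base64,{_p_hist(sub, name)}"/>'
        )
    sections.append("<h2>Significant proteins per contrast</h2>"
                    + _df_to_html(pd.DataFrame(summary_rows)))
    inter = intersection_counts(result, fdr_thr, fc_thr)
    if not inter.empty:
        sections.append("<h2>Intersections of significant sets</h2>" + _df_to_html(inter))

    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Differential expression report</title>"
        "<style>body{font-family:sans-serif;margin:2em;max-width:70em}"
        "table{border-collapse:collapse}td,th{padding:2px 8px;border-bottom:1px solid #ddd}"
        "</style></head><body>"
        "<h1>Differential expression analysis</h1>"
        f"<p>Thresholds: BH-FDR &le; {fdr_thr}, |log2FC| &ge; {fc_thr}. "
        "Proteins with contrast-relevant groups entirely unobserved are reported "
        "without fold change and p-value (or with a detection-limit fold change, "
        "flagged <code>imputed_fc</code>), never dropped.</p>"
        + "".join(sections)
        + "</body></html>"
    )
    path.write_text(html)
    return path


# ---------------------------------------------------------------------------
# result folder


def copy_inputs(out_root: str | Path, files: dict[str, Path], invocation: dict) -> Path:
    """Populate <out>/inputs/ with everything needed to replicate the run."""
    inputs = Path(out_root) / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    for label, src in files.items():
        if src is not None and Path(src).exists():
            shutil.copy2(src, inputs / Path(src).name)
    with open(inputs / "invocation.json", "w") as fh:
        json.dump(invocation, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return inputs
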