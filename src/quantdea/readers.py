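"""Parsers for quantification-software outputs.

Each reader turns one tool's report dialect into a :class:`TidyQuantTable`,
applying the recommended identification filters on the way in:

========  ==================  =========================================
software  input file          default filters
========  ==================  =========================================
DIA-NN    report.tsv          protein-group q-value <= 0.01
FragPipe  psm.tsv (TMT)       purity >= 0.5, PeptideProphet prob > 0.9
MaxQuant  peptides.txt        drop reverse and contaminant rows
========  ==================  =========================================

Dialect column names live in declarative tables (``_DIANN_COLUMNS`` etc.), not
in code paths, because upstream tools rename columns between versions; a new
version usually needs a one-line map update, not a parser rewrite.  External
packages can inject additional parsers through :func:`register_reader`
(e.g. Spectronaut ``BGS`` or FragPipe-DDA ``MSSTATS`` slots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .model import (
    INTENSITY,
    PEPTIDE,
    PROTEIN,
    SAMPLE,
    ColumnRoles,
    FilterSpec,
    TidyQuantTable,
    zeros_to_missing,
)

logger = logging.getLogger(__name__)


class ReaderError(ValueError):
    pass


@dataclass(frozen=True)
class ReaderSpec:
    key: str
    input_filename_pattern: str
    level: str  # "protein" or "peptide"
    parse: Callable[..., TidyQuantTable]
    default_filters: tuple[FilterSpec, ...] = ()

    def __post_init__(self):
        if self.level not in {"protein", "peptide"}:
            raise ValueError(f"level must be protein or peptide, got {self.level!r}")


_REGISTRY: dict[str, ReaderSpec] = {}


def register_reader(spec: ReaderSpec, overwrite: bool = False) -> None:
    if spec.key in _REGISTRY and not overwrite:
        raise ReaderError(f"reader key {spec.key!r} already registered (pass overwrite=True)")
    _REGISTRY[spec.key] = spec


def get_reader(key: str) -> ReaderSpec:
    try:
        return _REGISTRY[key]
    except KeyError:
        raise ReaderError(
            f"unknown software key {key!r}; registered keys: {sorted(_REGISTRY)}"
        ) from None


def list_readers() -> list[str]:
    return sorted(_REGISTRY)


def _resolve_columns(df: pd.DataFrame, colmap: dict[str, tuple[str, ...]],
                     required: tuple[str, ...]) -> dict[str, str]:
    resolved = {}
    for role, candidates in colmap.items():
        for c in candidates:
            if c in df.columns:
                resolved[role] = c
                break
    missing = [r for r in required if r not in resolved]
    if missing:
        raise ReaderError(
            f"required columns not found for roles {missing}; "
            f"expected one of {[colmap[m] for m in missing]}, file has {list(df.columns)}"
        )
    return resolved


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ReaderError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface any parse failure as fatal
        raise ReaderError(f"cannot read {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# DIA-NN / FragPipe-DIA long-format report.tsv

_DIANN_COLUMNS = {
    "sample": ("Run", "File.Name"),
    "protein": ("Protein.Group", "Protein.Ids"),
    "peptide": ("Stripped.Sequence", "Modified.Sequence"),
    "precursor": ("Precursor.Id",),
    "intensity": ("Precursor.Quantity", "Precursor.Normalised"),
    "pg_qvalue": ("PG.Q.Value", "Lib.PG.Q.Value"),
    "qvalue": ("Q.Value",),
}

DIANN_PG_QVALUE_DEFAULT = 0.01


def read_diann(
    path: str | Path,
    level: str = "protein",
    pg_qvalue: float = DIANN_PG_QVALUE_DEFAULT,
    precursor_qvalue: float | None = None,
) -> TidyQuantTable:
    """Parse a DIA-NN long-format ``report.tsv``.

    Rows failing the protein-group q-value filter are removed; optionally a
    precursor-level q-value filter is applied as well.  Charge states of the
    same stripped peptide collapse to the maximum intensity per sample;
    peptide-to-protein aggregation happens later (median polish).
    """
    df = _read_tsv(path)
    cols = _resolve_columns(
        df, _DIANN_COLUMNS, required=("sample", "protein", "peptide", "intensity", "pg_qvalue")
    )
    filters = [FilterSpec(cols["pg_qvalue"], pg_qvalue, "le")]
    if precursor_qvalue is not None and "qvalue" in cols:
        filters.append(FilterSpec(cols["qvalue"], precursor_qvalue, "le"))
    n0 = len(df)
    for f in filters:
        df = df.loc[f.mask(df)]
    logger.info("DIA-NN: %d of %d rows pass q-value filters", len(df), n0)

    long = pd.DataFrame(
        {
            SAMPLE: df[cols["sample"]].astype(str),
            PROTEIN: df[cols["protein"]].astype(str),
            PEPTIDE: df[cols["peptide"]].astype(str),
            INTENSITY: zeros_to_missing(df[cols["intensity"]]),
        }
    ).dropna(subset=[INTENSITY])
    # collapse charge states: max intensity per (sample, protein, peptide)
    long = (
        long.groupby([SAMPLE, PROTEIN, PEPTIDE], as_index=False, sort=False)[INTENSITY].max()
    )
    roles = ColumnRoles(qvalue_cols=tuple(filters))
    return TidyQuantTable(long, roles)


# ---------------------------------------------------------------------------
# FragPipe TMT psm.tsv

_FP_TMT_META_COLUMNS = (
    "Spectrum", "Spectrum File", "Peptide", "Modified Peptide", "Charge",
    "Retention", "Intensity", "Purity", "Probability", "PeptideProphet Probability",
    "Protein", "Protein ID", "Entry Name", "Gene", "Protein Description",
    "Mapped Genes", "Mapped Proteins", "Quan Usage", "Is Unique",
)

TMT_PURITY_DEFAULT = 0.5
TMT_PROBABILITY_DEFAULT = 0.9


def read_fragpipe_tmt(
    path: str | Path,
    level: str = "protein",
    purity: float = TMT_PURITY_DEFAULT,
    probability: float = TMT_PROBABILITY_DEFAULT,
) -> TidyQuantTable:
    """Parse a FragPipe TMT ``psm.tsv``.

    PSMs with isolation purity below the threshold (boundary retained) or
    PeptideProphet probability at or below the threshold (boundary excluded)
    are removed, the channel intensity columns are unpivoted to long format
    (sample = channel), and PSMs of the same peptide are summed per channel.
    """
    df = _read_tsv(path)
    prob_col = "PeptideProphet Probability" if "PeptideProphet Probability" in df.columns else "Probability"
    for needed in ("Peptide", "Protein", "Purity", prob_col):
        if needed not in df.columns:
            raise ReaderError(f"psm.tsv is missing required column {needed!r}")
    channel_cols = [
        c for c in df.columns
        if c not in _FP_TMT_META_COLUMNS and pd.api.types.is_numeric_dtype(df[c])
    ]
    if not channel_cols:
        raise ReaderError(
            f"no TMT channel intensity columns detected; file columns: {list(df.columns)}"
        )
    filters = (
        FilterSpec("Purity", purity, "ge"),
        FilterSpec(prob_col, probability, "gt"),
    )
    n0 = len(df)
    for f in filters:
        df = df.loc[f.mask(df)]
    logger.info("FragPipe TMT: %d of %d PSMs pass purity/probability filters", len(df), n0)

    long = df.melt(
        id_vars=["Peptide", "Protein"],
        value_vars=channel_cols,
        var_name=SAMPLE,
        value_name=INTENSITY,
    )
    long[INTENSITY] = zeros_to_missing(long[INTENSITY])
    long = long.dropna(subset=[INTENSITY])
    long = long.rename(columns={"Peptide": PEPTIDE, "Protein": PROTEIN})
    # PSMs of the same peptide are additive evidence: sum per channel
    long = (
        long.groupby([SAMPLE, PROTEIN, PEPTIDE], as_index=False, sort=False)[INTENSITY].sum()
    )
    return TidyQuantTable(long, ColumnRoles(qvalue_cols=filters))


# ---------------------------------------------------------------------------
# MaxQuant peptides.txt

_MQ_INTENSITY_PREFIX = "Intensity "
_MQ_REVERSE = "Reverse"
_MQ_CONTAMINANT = ("Potential contaminant", "Contaminant")


def read_maxquant_peptides(path: str | Path, level: str = "protein") -> TidyQuantTable:
    """Parse a MaxQuant ``peptides.txt`` (wide per-sample Intensity columns)."""
    df = _read_tsv(path)
    if "Sequence" not in df.columns:
        raise ReaderError("peptides.txt is missing the 'Sequence' column")
    protein_col = next(
        (c for c in ("Leading razor protein", "Proteins") if c in df.columns), None
    )
    if protein_col is None:
        raise ReaderError("peptides.txt has neither 'Leading razor protein' nor 'Proteins'")
    intensity_cols = [c for c in df.columns if c.startswith(_MQ_INTENSITY_PREFIX)]
    if not intensity_cols:
        raise ReaderError(
            f"no per-sample '{_MQ_INTENSITY_PREFIX}<sample>' columns found in peptides.txt"
        )
    n0 = len(df)
    flagged = pd.Series(False, index=df.index)
    for col in (_MQ_REVERSE, *_MQ_CONTAMINANT):
        if col in df.columns:
            flagged |= df[col].fillna("").astype(str).str.strip() == "+"
    df = df.loc[~flagged]
    logger.info("MaxQuant: removed %d reverse/contaminant rows of %d", n0 - len(df), n0)

    long = df.melt(
        id_vars=["Sequence", protein_col],
        value_vars=intensity_cols,
        var_name=SAMPLE,
        value_name=INTENSITY,
    )
    long[SAMPLE] = long[SAMPLE].str.slice(len(_MQ_INTENSITY_PREFIX))
    long[INTENSITY] = zeros_to_missing(long[INTENSITY])
    long = long.dropna(subset=[INTENSITY])
    long = long.rename(columns={"Sequence": PEPTIDE, protein_col: PROTEIN})
    long = (
        long.groupby([SAMPLE, PROTEIN, PEPTIDE], as_index=False, sort=False)[INTENSITY].max()
    )
    return TidyQuantTable(long, ColumnRoles())


# ---------------------------------------------------------------------------
# registry population and directory-level helpers

def _builtin_specs() -> list[ReaderSpec]:
    specs = []
    for key, level in (("DIANN", "protein"), ("DIANN_PEPTIDE", "peptide")):
        specs.append(
            ReaderSpec(
                key=key,
                input_filename_pattern="report.tsv",
                level=level,
                parse=read_diann,
                default_filters=(FilterSpec("PG.Q.Value", DIANN_PG_QVALUE_DEFAULT, "le"),),
            )
        )
    for key, level in (("FP_TMT", "protein"), ("FP_TMT_PEPTIDE", "peptide")):
        specs.append(
            ReaderSpec(
                key=key,
                input_filename_pattern="psm.tsv",
                level=level,
                parse=read_fragpipe_tmt,
                default_filters=(
                    FilterSpec("Purity", TMT_PURITY_DEFAULT, "ge"),
                    FilterSpec("PeptideProphet Probability", TMT_PROBABILITY_DEFAULT, "gt"),
                ),
            )
        )
    for key, level in (("MAXQUANT", "protein"), ("MAXQUANT_PEPTIDE", "peptide")):
        specs.append(
            ReaderSpec(
                key=key,
                input_filename_pattern="peptide*.txt",
                level=level,
                parse=read_maxquant_peptides,
            )
        )
    return specs


for _spec in _builtin_specs():
    register_reader(_spec, overwrite=True)


def find_input_file(input_dir: str | Path, software_key: str) -> Path:
    spec = get_reader(software_key)
    input_dir = Path(input_dir)
    hits = sorted(input_dir.glob(spec.input_filename_pattern))
    # case-insensitive fallback (FragPipe writes PSM.tsv on some platforms)
    if not hits:
        pat = spec.input_filename_pattern.lower()
        hits = sorted(
            p for p in input_dir.iterdir()
            if p.is_file() and Path(p.name.lower()).match(pat)
        )
    if not hits:
        raise ReaderError(
            f"no input matching {spec.input_filename_pattern!r} for software "
            f"{software_key!r} in {input_dir}"
        )
    if len(hits) > 1:
        logger.warning("multiple candidate inputs %s; using %s", hits, hits[0])
    return hits[0]


def read_quant_table(input_dir: str | Path, software_key: str, **filter_overrides) -> TidyQuantTable:
    """Locate and parse the quantification report for a software key."""
    spec = get_reader(software_key)
    path = find_input_file(input_dir, software_key)
    return spec.parse(path, level=spec.level, **filter_overrides)


def list_sample_ids(input_dir: str | Path, software_key: str) -> list[str]:
    """Extract the sample identifiers (raw files or TMT channels) from the report.

    Identifiers are returned unique, order-stable and verbatim — this is what
    the annotation template is seeded with, so it must match the data exactly.
    """
    spec = get_reader(software_key)
    path = find_input_file(input_dir, software_key)
    if spec.parse is read_fragpipe_tmt:
        df = _read_tsv(path)
        channels = [
            c for c in df.columns
            if c not in _FP_TMT_META_COLUMNS and pd.api.types.is_numeric_dtype(df[c])
        ]
        ids = channels
    elif spec.parse is read_maxquant_peptides:
        df = _read_tsv(path)
        ids = [
            c[len(_MQ_INTENSITY_PREFIX):]
            for c in df.columns
            if c.startswith(_MQ_INTENSITY_PREFIX)
        ]
    else:
        df = _read_tsv(path)
        cols = _resolve_columns(df, _DIANN_COLUMNS, required=("sample",))
        ids = list(pd.unique(df[cols["sample"]].astype(str)))
    if not ids:
        logger.warning("no sample identifiers found in %s", path)
    return list(dict.fromkeys(ids))
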