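"""Core data model shared by all pipeline stages.

Every reader normalizes its dialect into a :class:`TidyQuantTable`: one row per
(sample, protein, peptide) observation with a strictly positive, linear-scale
intensity (unless already log-transformed).  The table plus its
:class:`ColumnRoles` is the single currency passed between ingestion,
normalization, summarization and modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names used internally by every stage
SAMPLE = "sample_id"
PROTEIN = "protein_id"
PEPTIDE = "peptide_id"
INTENSITY = "intensity"


@dataclass(frozen=True)
class FilterSpec:
    """A row-level score filter: keep rows where ``column <op> threshold``.

    ``direction`` is one of ``le``, ``lt``, ``ge``, ``gt``.
    """

    column: str
    threshold: float
    direction: str

    _OPS = {
        "le": lambda v, t: v <= t,
        "lt": lambda v, t: v < t,
        "ge": lambda v, t: v >= t,
        "gt": lambda v, t: v > t,
    }

    def mask(self, df: pd.DataFrame) -> pd.Series:
        if self.column not in df.columns:
            raise KeyError(f"filter column {self.column!r} not present in table")
        vals = pd.to_numeric(df[self.column], errors="coerce")
        # rows with a missing score pass (no evidence against them)
        return vals.isna() | self._OPS[self.direction](vals, self.threshold)


@dataclass(frozen=True)
class ColumnRoles:
    """Annotation of the columns in the tidy quantification table."""

    sample_id: str = SAMPLE
    protein_id: str = PROTEIN
    peptide_id: str | None = PEPTIDE
    intensity: str = INTENSITY
    qvalue_cols: tuple[FilterSpec, ...] = ()
    is_log_transformed: bool = False

    def key_columns(self) -> list[str]:
        cols = [self.sample_id, self.protein_id]
        if self.peptide_id is not None:
            cols.append(self.peptide_id)
        return cols


@dataclass
class TidyQuantTable:
    """Long-format quantification table with column-role metadata.

    Invariants enforced at construction:

    * role columns exist;
    * intensity 0 and NA are both treated as missing and dropped;
    * no duplicate (sample, protein, peptide) key.
    """

    data: pd.DataFrame
    roles: ColumnRoles = field(default_factory=ColumnRoles)

    def __post_init__(self) -> None:
        r = self.roles
        needed = r.key_columns() + [r.intensity]
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValueError(f"table is missing role columns: {missing}")
        df = self.data
        inten = pd.to_numeric(df[r.intensity], errors="coerce")
        keep = inten.notna()
        if not r.is_log_transformed:
            keep &= inten > 0
        if (~keep).any():
            logger.debug("dropping %d zero/missing intensity rows", int((~keep).sum()))
            df = df.loc[keep]
        df = df.assign(**{r.intensity: inten[keep]})
        dup = df.duplicated(subset=r.key_columns())
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate {tuple(r.key_columns())} keys after ingestion"
            )
        self.data = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data[self.roles.sample_id]))

    @property
    def proteins(self) -> list[str]:
        return list(pd.unique(self.data[self.roles.protein_id]))

    def __len__(self) -> int:
        return len(self.data)

    def with_data(self, data: pd.DataFrame, **role_changes) -> "TidyQuantTable":
        roles = replace(self.roles, **role_changes) if role_changes else self.roles
        return TidyQuantTable(data, roles)


class AnnotationMismatchError(ValueError):
    """The sample annotation shares no sample identifiers with the data."""


@dataclass
class ValidationReport:
    samples_only_in_data: list[str]
    samples_only_in_annotation: list[str]
    duplicate_keys: int
    proteins_without_observation: list[str]

    @property
    def n_mismatches(self) -> int:
        return len(self.samples_only_in_data) + len(self.samples_only_in_annotation)


def validate_table(table: TidyQuantTable, annotation) -> ValidationReport:
    """Cross-check a parsed table against the sample annotation.

    Raises :class:`AnnotationMismatchError` only when the two sample sets are
    disjoint; every other discrepancy is reported (and logged) but tolerated —
    extra data samples are expected to be dropped by the caller.
    """
    data_samples = set(table.samples)
    ann_samples = set(annotation.sample_ids)
    if not data_samples & ann_samples:
        raise AnnotationMismatchError(
            "annotation does not match data: "
            f"annotation samples {sorted(ann_samples)} vs data samples {sorted(data_samples)}"
        )
    only_data = sorted(data_samples - ann_samples)
    only_ann = sorted(ann_samples - data_samples)
    if only_data:
        logger.warning("samples present in data but not annotation (dropped): %s", only_data)
    if only_ann:
        logger.warning("samples present in annotation but not data: %s", only_ann)
    counts = table.data.groupby(table.roles.protein_id, observed=True).size()
    return ValidationReport(
        samples_only_in_data=only_data,
        samples_only_in_annotation=only_ann,
        duplicate_keys=0,
        proteins_without_observation=sorted(counts.index[counts < 1]),
    )


def restrict_to_annotation(table: TidyQuantTable, annotation) -> TidyQuantTable:
    """Drop rows whose sample is not listed in the annotation."""
    keep = table.data[table.roles.sample_id].isin(set(annotation.sample_ids))
    return table.with_data(table.data.loc[keep].reset_index(drop=True))


def as_matrix(table: TidyQuantTable, index: str | list[str] | None = None) -> pd.DataFrame:
    """Pivot the long table to an (index x sample) matrix of intensities."""
    r = table.roles
    if index is None:
        index = [r.protein_id] + ([r.peptide_id] if r.peptide_id else [])
    return table.data.pivot_table(
        index=index, columns=r.sample_id, values=r.intensity, aggfunc="first", observed=True
    )


def zeros_to_missing(values: pd.Series) -> pd.Series:
    """Map 0 and non-numeric to NaN (both mean "not observed" in these dialects)."""
    v = pd.to_numeric(values, errors="coerce")
    return v.mask(v == 0, np.nan)
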