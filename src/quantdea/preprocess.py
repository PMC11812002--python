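"""Intensity transformation, peptide-to-protein summarization and QC statistics.

The default normalization, ``robscale``, log2-transforms intensities and then
robustly standardizes each sample (median/MAD) before rescaling by the mean
sample MAD and re-adding the grand median — removing per-sample loading and
scale differences while keeping the values in interpretable log2 units.

Protein abundances are estimated from the peptide x sample matrix of each
protein with Tukey's median polish: an iterative decomposition

    y_ij = overall + row_i + col_j + residual_ij

by alternating row and column median sweeps.  The protein's abundance in
sample *j* is ``overall + col_j``; being median-based, it is robust to
single outlier peptides, unlike a mean or a sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import TidyQuantTable

logger = logging.getLogger(__name__)

MEDIAN_POLISH_TOL = 1e-6
MEDIAN_POLISH_MAX_ITER = 10


# ---------------------------------------------------------------------------
# normalization


def log2_and_normalize(table: TidyQuantTable, method: str = "robscale") -> TidyQuantTable:
    """Log2-transform and normalize per-sample intensities.

    method
        ``robscale`` (default): per sample subtract the median and divide by
        the MAD, then multiply by the mean of the sample MADs and add back the
        grand median.  ``quantile``: classical quantile normalization over the
        observed values.  ``none``: log2 only.
    """
    if method not in {"robscale", "quantile", "none"}:
        raise ValueError(f"unknown normalization method {method!r}")
    r = table.roles
    if r.is_log_transformed:
        raise ValueError("table is already log-transformed")
    df = table.data.copy()
    df[r.intensity] = np.log2(df[r.intensity].to_numpy(dtype=float))

    if method == "robscale":
        df[r.intensity] = _robscale(df, r.sample_id, r.intensity)
    elif method == "quantile":
        df[r.intensity] = _quantile_normalize(df, r.sample_id, r.intensity)

    return table.with_data(df, is_log_transformed=True)


def _robscale(df: pd.DataFrame, sample_col: str, value_col: str) -> pd.Series:
    values = df[value_col]
    grand_median = float(values.median())
    grouped = df.groupby(sample_col, observed=True)[value_col]
    medians = grouped.transform("median")
    mads = grouped.transform(
        lambda v: stats.median_abs_deviation(v, scale="normal", nan_policy="omit")
    )
    counts = grouped.transform("size")
    usable = (counts >= 3) & (mads > 0)
    skipped = df.loc[~usable, sample_col].unique()
    if len(skipped):
        logger.warning("robscale skipped for samples with <3 values or zero MAD: %s",
                       list(skipped))
    # mean MAD over normalizable samples restores an interpretable scale
    mean_mad = float(
        df.loc[usable].groupby(sample_col, observed=True)[value_col]
        .apply(lambda v: stats.median_abs_deviation(v, scale="normal"))
        .mean()
    )
    out = values.copy()
    out[usable] = (values[usable] - medians[usable]) / mads[usable] * mean_mad + grand_median
    return out


def _quantile_normalize(df: pd.DataFrame, sample_col: str, value_col: str) -> pd.Series:
    # reference distribution: mean of per-sample quantiles on a common grid
    grid = np.linspace(0, 1, 101)
    per_sample_q = df.groupby(sample_col, observed=True)[value_col].apply(
        lambda v: np.quantile(v, grid)
    )
    reference = np.mean(np.vstack(per_sample_q.to_numpy()), axis=0)

    def map_sample(v: pd.Series) -> pd.Series:
        if len(v) < 3:
            logger.warning("quantile normalization skipped for a sample with <3 values")
            return v
        ranks = v.rank(method="average")
        frac = (ranks - 1) / (len(v) - 1) if len(v) > 1 else ranks * 0
        return pd.Series(np.interp(frac, grid, reference), index=v.index)

    return df.groupby(sample_col, observed=True)[value_col].transform(map_sample)


# ---------------------------------------------------------------------------
# Tukey median polish


def _nanmedian_2d(z: np.ndarray, axis: int) -> np.ndarray:
    """NaN-aware median along one axis of a 2-D array.

    Equivalent to ``np.nanmedian`` (even counts average the two central
    values) but avoids its masked-array path, which dominates runtime when
    called once per protein; all-NaN slices yield NaN without warning.
    """
    zs = np.sort(z, axis=axis)  # NaNs sort to the end
    nobs = z.shape[axis] - np.isnan(z).sum(axis=axis)
    lo = np.expand_dims(np.maximum((nobs - 1) // 2, 0), axis)
    hi = np.expand_dims(nobs // 2, axis)
    med = 0.5 * (
        np.take_along_axis(zs, lo, axis=axis).squeeze(axis)
        + np.take_along_axis(zs, np.minimum(hi, z.shape[axis] - 1), axis=axis).squeeze(axis)
    )
    return np.where(nobs == 0, np.nan, med)


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray

    def fitted_abundance(self) -> np.ndarray:
        """Per-column abundance estimate: overall + column effect."""
        return self.overall + self.col_effects


def median_polish(
    mat: np.ndarray,
    tol: float = MEDIAN_POLISH_TOL,
    max_iter: int = MEDIAN_POLISH_MAX_ITER,
) -> MedianPolishResult:
    """Tukey median polish of a (rows x cols) matrix with NaN for missing cells.

    Alternates row- and column-median sweeps until the change in the sum of
    absolute residuals drops below ``tol`` or ``max_iter`` is reached.  For
    every observed cell ``overall + row + col + residual`` reproduces the
    input exactly (the sweeps only move mass between the components).
    """
    z = np.asarray(mat, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish expects a non-empty 2-D matrix")
    if np.all(np.isnan(z)):
        raise ValueError("median_polish: all cells are missing")
    z = z.copy()
    nr, nc = z.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    last_sum = np.nansum(np.abs(z))
    for _ in range(max_iter):
        rdelta = _nanmedian_2d(z, axis=1)
        rdelta = np.where(np.isnan(rdelta), 0.0, rdelta)
        z -= rdelta[:, None]
        row_eff += rdelta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cdelta = _nanmedian_2d(z, axis=0)
        cdelta = np.where(np.isnan(cdelta), 0.0, cdelta)
        z -= cdelta[None, :]
        col_eff += cdelta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        new_sum = np.nansum(np.abs(z))
        if abs(new_sum - last_sum) < tol:
            break
        last_sum = new_sum
    return MedianPolishResult(overall=overall, row_effects=row_eff,
                              col_effects=col_eff, residuals=z)


def summarize_proteins(table: TidyQuantTable) -> TidyQuantTable:
    """Summarize normalized peptide abundances to one value per (protein, sample).

    Each protein's peptide x sample matrix is median-polished; the abundance
    in a sample is ``overall + column effect``, reported only for samples with
    at least one observed peptide.
    """
    r = table.roles
    if r.peptide_id is None:
        raise ValueError("summarize_proteins requires a peptide-level table")
    if not r.is_log_transformed:
        raise ValueError("summarize_proteins expects log-transformed intensities")
    records = []
    for protein, sub in table.data.groupby(r.protein_id, observed=True, sort=True):
        scodes, samples = pd.factorize(sub[r.sample_id])
        pcodes, _ = pd.factorize(sub[r.peptide_id])
        mat = np.full((pcodes.max() + 1, len(samples)), np.nan)
        mat[pcodes, scodes] = sub[r.intensity].to_numpy(dtype=float)
        abundance = median_polish(mat).fitted_abundance()
        for sample, value in zip(samples, abundance):
            records.append((sample, protein, value))
    out = pd.DataFrame(records, columns=[r.sample_id, r.protein_id, r.intensity])
    return TidyQuantTable(out, roles=_protein_roles(table))


def _protein_roles(table: TidyQuantTable):
    from dataclasses import replace

    return replace(table.roles, peptide_id=None)


# ---------------------------------------------------------------------------
# QC statistics


@dataclass
class QCStats:
    peptides_per_protein: pd.DataFrame   # protein_id, n_peptides_experiment
    peptides_per_sample: pd.DataFrame    # protein_id x sample counts (wide)
    group_stats: pd.DataFrame            # protein_id, group, n_observed, n_missing, cv_percent


def qc_statistics(
    table: TidyQuantTable,
    annotation,
    protein_table: TidyQuantTable | None = None,
) -> QCStats:
    """Peptide counts and per-group missingness / CV statistics.

    CV is computed on linear-scale intensities (back-transformed when the
    input is log2), per protein per group, and left empty for groups with
    fewer than two observations.  Missingness counts use the protein-level
    table when provided (a protein is missing in a sample if no peptide was
    observed there).
    """
    r = table.roles
    pep = table.data
    if r.peptide_id is not None:
        per_protein = (
            pep.groupby(r.protein_id, observed=True)[r.peptide_id]
            .nunique()
            .rename("n_peptides_experiment")
            .reset_index()
        )
        per_sample = (
            pep.groupby([r.protein_id, r.sample_id], observed=True)[r.peptide_id]
            .nunique()
            .unstack(r.sample_id, fill_value=0)
        )
    else:
        per_protein = (
            pep.groupby(r.protein_id, observed=True)
            .size()
            .rename("n_peptides_experiment")
            .reset_index()
        )
        per_sample = (
            pep.groupby([r.protein_id, r.sample_id], observed=True)
            .size()
            .unstack(r.sample_id, fill_value=0)
        )

    ptab = protein_table if protein_table is not None else _protein_totals(table)
    pr = ptab.roles
    pdata = ptab.data.copy()
    values = pdata[pr.intensity].to_numpy(dtype=float)
    if pr.is_log_transformed:
        values = np.exp2(values)
    pdata["_linear"] = values
    group_of = annotation.group_of()
    group_sizes = annotation.table.groupby("group", observed=True).size()
    pdata["group"] = pdata[pr.sample_id].map(group_of)
    pdata = pdata.dropna(subset=["group"])

    rows = []
    grouped = pdata.groupby([pr.protein_id, "group"], observed=True)["_linear"]
    agg = grouped.agg(["count", "mean", "std"])
    all_proteins = pd.unique(ptab.data[pr.protein_id])
    for protein in all_proteins:
        for group, size in group_sizes.items():
            if (protein, group) in agg.index:
                n, mean, sd = agg.loc[(protein, group)]
                n = int(n)
                cv = 100.0 * sd / mean if n >= 2 and mean > 0 else np.nan
            else:
                n, cv = 0, np.nan
            rows.append(
                {"protein_id": protein, "group": group, "n_observed": n,
                 "n_missing": int(size) - n, "cv_percent": cv}
            )
    return QCStats(
        peptides_per_protein=per_protein,
        peptides_per_sample=per_sample,
        group_stats=pd.DataFrame(rows),
    )


def _protein_totals(table: TidyQuantTable) -> TidyQuantTable:
    r = table.roles
    if r.peptide_id is None:
        return table
    totals = (
        table.data.groupby([r.sample_id, r.protein_id], as_index=False, observed=True)[
            r.intensity
        ].sum()
    )
    return TidyQuantTable(totals, roles=_protein_roles(table))


# ---------------------------------------------------------------------------
# sample-size estimation


def sample_size_estimate(
    sd_values: np.ndarray | list[float],
    deltas: tuple[float, ...] = (0.5, 1.0, 2.0),
    alpha: float = 0.05,
    power: float = 0.8,
    sd_probs: tuple[float, ...] = (0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Required replicates per group for two-group comparisons.

    Uses the normal-approximation two-sample formula
    ``n = ceil(2 sigma^2 (z_{1-alpha/2} + z_power)^2 / delta^2)`` (minimum 2)
    at the given quantiles of the empirical within-group standard deviation
    distribution (log2 scale) and the given detectable log2 fold changes.
    """
    if any(d <= 0 for d in deltas):
        raise ValueError("deltas must be positive log2 fold changes")
    sds = np.asarray(sd_values, dtype=float)
    sds = sds[~np.isnan(sds)]
    if sds.size == 0:
        raise ValueError("no within-group standard deviations available")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    rows = []
    for prob in sd_probs:
        sigma = float(np.quantile(sds, prob))
        for delta in deltas:
            n = max(2, math.ceil(2 * sigma**2 * z**2 / delta**2))
            rows.append(
                {"sd_quantile": prob, "sigma": sigma, "delta": delta,
                 "alpha": alpha, "power": power, "n_per_group": n}
            )
    return pd.DataFrame(rows)


def within_group_sds(protein_table: TidyQuantTable, annotation) -> np.ndarray:
    """Empirical within-group standard deviations (log2) pooled over proteins."""
    r = protein_table.roles
    df = protein_table.data.copy()
    df["group"] = df[r.sample_id].map(annotation.group_of())
    sds = (
        df.dropna(subset=["group"])
        .groupby([r.protein_id, "group"], observed=True)[r.intensity]
        .std()
        .dropna()
    )
    return sds.to_numpy()
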