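"""Per-protein linear models, moderated contrast tests and FDR control.

Each protein's summarized log2 abundance is regressed on group indicators
(cell means coding, no intercept), with additive subject indicators when the
design is paired/blocked.  Residual variances are moderated by shrinking each
protein's estimate toward the ensemble mean with a prior worth ``prior_df``
degrees of freedom:

    s2_shrunk = (prior_df * prior_var + df * s2) / (prior_df + df)

and contrast tests use the t distribution with ``df + prior_df`` degrees of
freedom.  ``prior_df = 0`` recovers ordinary per-protein statistics.

Missingness policy: proteins are never dropped.  When a contrast involves a
group with zero observations, the contrast is either reported without fold
change and p-value (``omit``) or the missing group's mean is set to the
dataset-wide detection limit so a fold-change direction can still be reported
(``model``, the default); imputed fold changes carry no p-value, since they
have no sampling-variance basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ContrastSet, ContrastVector, SampleAnnotation
from .model import TidyQuantTable
from .preprocess import QCStats

logger = logging.getLogger(__name__)

PRIOR_DF_DEFAULT = 10.0
DETECTION_QUANTILE_DEFAULT = 0.05

STATUS_MODELLED = "modelled"
STATUS_IMPUTED = "imputed_fc"
STATUS_NOT_ESTIMABLE = "not_estimable"


@dataclass
class ModelFit:
    protein_id: str
    group_means: dict[str, float]
    sigma2: float
    df_resid: float
    estimable_groups: list[str]
    n_obs: int
    # unscaled covariance of the group coefficients (pinv(X'X) restricted to
    # group columns) and the row-space projector for estimability checks
    cov_unscaled: np.ndarray = field(repr=False, default=None)
    group_index: dict[str, int] = field(repr=False, default_factory=dict)
    projector: np.ndarray = field(repr=False, default=None)


@dataclass
class ModerationParams:
    prior_df: float
    prior_var: float

    def shrink(self, sigma2: float, df: float) -> tuple[float, float]:
        """Return (shrunken sigma2, effective df) for one protein."""
        if self.prior_df == 0:
            return sigma2, df
        if df <= 0 or np.isnan(sigma2):
            return self.prior_var, self.prior_df
        s2 = (self.prior_df * self.prior_var + df * sigma2) / (self.prior_df + df)
        return s2, df + self.prior_df


@dataclass
class ContrastResult:
    protein_id: str
    contrast_name: str
    log2fc: float | None
    se: float | None
    t: float | None
    df: float
    p: float | None
    status: str
    p_adj: float | None = None


def fit_group_model(
    y: pd.Series,
    annotation: SampleAnnotation,
    protein_id: str = "",
) -> ModelFit:
    """Least-squares fit of one protein's abundances on group (and subject) indicators.

    ``y`` is indexed by sample id; missing samples are simply absent.  Groups
    without any observation are excluded from ``estimable_groups``.  With a
    subject column, subject fixed effects (first observed subject as
    reference) absorb between-subject shifts; contrasts whose coefficients
    sum to zero are unaffected by the reference choice.
    """
    y = y.dropna()
    if len(y) == 0:
        raise ValueError(f"protein {protein_id!r}: no observations")
    group_of = annotation.group_of()
    groups = [g for g in annotation.groups if g in set(group_of.loc[y.index])]
    gidx = {g: j for j, g in enumerate(groups)}
    n = len(y)
    X_group = np.zeros((n, len(groups)))
    for i, s in enumerate(y.index):
        X_group[i, gidx[group_of[s]]] = 1.0

    X = X_group
    subject_of = annotation.subject_of()
    if subject_of is not None:
        subj = subject_of.loc[y.index]
        levels = list(dict.fromkeys(subj))
        if len(levels) > 1:
            X_subj = np.zeros((n, len(levels) - 1))
            for i, s in enumerate(subj):
                k = levels.index(s)
                if k > 0:
                    X_subj[i, k - 1] = 1.0
            X = np.hstack([X_group, X_subj])

    xtx = X.T @ X
    xtx_pinv = np.linalg.pinv(xtx)
    beta = xtx_pinv @ X.T @ y.to_numpy(dtype=float)
    fitted = X @ beta
    rss = float(np.sum((y.to_numpy(dtype=float) - fitted) ** 2))
    rank = int(np.linalg.matrix_rank(X))
    df_resid = n - rank
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    projector = xtx @ xtx_pinv  # projects onto the row space of X
    return ModelFit(
        protein_id=protein_id,
        group_means={g: float(beta[j]) for g, j in gidx.items()},
        sigma2=sigma2,
        df_resid=df_resid,
        estimable_groups=groups,
        n_obs=n,
        cov_unscaled=xtx_pinv,
        group_index=gidx,
        projector=projector,
    )


def moderate_variance(fits: list[ModelFit], prior_df: float = PRIOR_DF_DEFAULT) -> ModerationParams:
    """Moment-based empirical-Bayes prior from the ensemble of residual variances."""
    if prior_df < 0:
        raise ValueError("prior_df must be >= 0")
    sigma2 = np.array([f.sigma2 for f in fits if f.df_resid >= 1 and not np.isnan(f.sigma2)])
    if sigma2.size == 0:
        raise ValueError("no residual degrees of freedom; add replicates")
    return ModerationParams(prior_df=prior_df, prior_var=float(np.mean(sigma2)))


def _extended_coef(fit: ModelFit, c: ContrastVector) -> np.ndarray:
    p = fit.cov_unscaled.shape[0]
    ce = np.zeros(p)
    for g, coef in c.coefficients.items():
        if abs(coef) > 0:
            ce[fit.group_index[g]] = coef
    return ce


def test_contrast(
    fit: ModelFit,
    c: ContrastVector,
    moderation: ModerationParams | None = None,
) -> ContrastResult:
    """Estimate and test one contrast on a fitted protein model."""
    needed = c.nonzero_groups()
    missing = [g for g in needed if g not in fit.estimable_groups]
    if missing:
        raise ValueError(
            f"contrast {c.name!r} involves unobserved groups {missing}; "
            "route through handle_missing_groups"
        )
    ce = _extended_coef(fit, c)
    # estimability under a possibly singular design: c must lie in row(X)
    if fit.projector is not None and not np.allclose(fit.projector @ ce, ce, atol=1e-8):
        return ContrastResult(fit.protein_id, c.name, None, None, None,
                              fit.df_resid, None, STATUS_NOT_ESTIMABLE)
    log2fc = float(sum(coef * fit.group_means[g] for g, coef in c.coefficients.items()
                       if abs(coef) > 0))
    mod = moderation or ModerationParams(prior_df=0.0, prior_var=1.0)
    sigma2, df_eff = mod.shrink(fit.sigma2, fit.df_resid)
    if np.isnan(sigma2) or df_eff <= 0:
        return ContrastResult(fit.protein_id, c.name, log2fc, None, None,
                              fit.df_resid, None, STATUS_NOT_ESTIMABLE)
    var_c = float(ce @ fit.cov_unscaled @ ce) * sigma2
    se = float(np.sqrt(max(var_c, 0.0)))
    if se == 0:
        # zero residual variance and no prior: a fold change without a test
        logger.debug("protein %s contrast %s: zero variance", fit.protein_id, c.name)
        return ContrastResult(fit.protein_id, c.name, log2fc, 0.0, None,
                              df_eff, None, STATUS_MODELLED)
    t = log2fc / se
    p = float(2 * stats.t.sf(abs(t), df_eff))
    return ContrastResult(fit.protein_id, c.name, log2fc, se, float(t), df_eff, p,
                          STATUS_MODELLED)


def handle_missing_groups(
    fit: ModelFit,
    c: ContrastVector,
    strategy: str = "model",
    detection_limit: float | None = None,
) -> ContrastResult:
    """Contrast evaluation when a contrast-relevant group has zero observations.

    ``omit``: report the protein without fold change and p-value.  ``model``:
    substitute the detection limit (a low log2 abundance, by default the 5th
    percentile of all observed values) for the missing group's mean so a fold
    change can still be reported; no p-value is attached.
    """
    if strategy not in {"model", "omit"}:
        raise ValueError(f"unknown missing-group strategy {strategy!r}")
    needed = c.nonzero_groups()
    observed = [g for g in needed if g in fit.estimable_groups]
    if not observed or strategy == "omit" or detection_limit is None:
        return ContrastResult(fit.protein_id, c.name, None, None, None,
                              fit.df_resid, None, STATUS_NOT_ESTIMABLE)
    log2fc = float(
        sum(
            coef * (fit.group_means[g] if g in fit.estimable_groups else detection_limit)
            for g, coef in c.coefficients.items()
            if abs(coef) > 0
        )
    )
    return ContrastResult(fit.protein_id, c.name, log2fc, None, None,
                          fit.df_resid, None, STATUS_IMPUTED)


def adjust_fdr(p: pd.Series | np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched."""
    arr = np.asarray(p, dtype=float)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class DEAResult:
    """Everything one differential-expression run produced."""

    stats: pd.DataFrame             # per (protein, contrast) test results
    abundance: pd.DataFrame         # proteins x samples, log2
    group_means: pd.DataFrame       # proteins x groups
    qc: QCStats | None
    protein_info: pd.DataFrame | None
    annotation: SampleAnnotation
    contrasts: ContrastSet
    config: dict = field(default_factory=dict)
    detection_limit: float = np.nan

    def contrast_stats(self, name: str) -> pd.DataFrame:
        return self.stats[self.stats["contrast"] == name]


def run_dea(
    protein_table: TidyQuantTable,
    annotation: SampleAnnotation,
    contrasts: ContrastSet,
    prior_df: float = PRIOR_DF_DEFAULT,
    missing_strategy: str = "model",
    detection_quantile: float = DETECTION_QUANTILE_DEFAULT,
    qc: QCStats | None = None,
    protein_info: pd.DataFrame | None = None,
    config: dict | None = None,
) -> DEAResult:
    """Fit every protein, evaluate every contrast, and BH-adjust per contrast.

    Deterministic given inputs; every protein appears exactly once per
    contrast in the output, whatever its missingness pattern.
    """
    r = protein_table.roles
    wide = protein_table.data.pivot_table(
        index=r.protein_id, columns=r.sample_id, values=r.intensity,
        aggfunc="first", observed=True,
    ).sort_index()
    ann_samples = [s for s in annotation.sample_ids if s in wide.columns]
    wide = wide[ann_samples]
    detection_limit = float(np.nanquantile(wide.to_numpy(), detection_quantile))

    fits: dict[str, ModelFit] = {}
    for protein, row in wide.iterrows():
        fits[protein] = fit_group_model(row, annotation, protein_id=str(protein))
    moderation = moderate_variance(list(fits.values()), prior_df=prior_df)

    records: list[ContrastResult] = []
    for c in contrasts:
        for protein, fit in fits.items():
            needed = c.nonzero_groups()
            if all(g in fit.estimable_groups for g in needed):
                res = test_contrast(fit, c, moderation)
            else:
                res = handle_missing_groups(fit, c, strategy=missing_strategy,
                                            detection_limit=detection_limit)
            records.append(res)

    stats_df = pd.DataFrame(
        {
            "protein_id": [x.protein_id for x in records],
            "contrast": [x.contrast_name for x in records],
            "log2fc": [x.log2fc for x in records],
            "se": [x.se for x in records],
            "t": [x.t for x in records],
            "df": [x.df for x in records],
            "p": [x.p for x in records],
            "status": [x.status for x in records],
        }
    )
    stats_df["p_adj"] = np.nan
    for name in contrasts.names():
        m = stats_df["contrast"] == name
        stats_df.loc[m, "p_adj"] = adjust_fdr(stats_df.loc[m, "p"])

    group_means = pd.DataFrame(
        {g: {p: f.group_means.get(g, np.nan) for p, f in fits.items()}
         for g in annotation.groups}
    )
    group_means.index.name = "protein_id"

    return DEAResult(
        stats=stats_df,
        abundance=wide,
        group_means=group_means,
        qc=qc,
        protein_info=protein_info,
        annotation=annotation,
        contrasts=contrasts,
        config=dict(config or {}),
        detection_limit=detection_limit,
    )
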