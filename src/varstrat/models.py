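"""Association models on pooled multi-group samples.

Implements the two linear models whose contrast defines variance
stratification:

* the *homogeneous-variance* model — ordinary least squares with a single
  residual-variance parameter shared by all analysis groups, the default
  in pooled GWAS; and
* the *stratified-variance* model — feasible generalized least squares
  (FGLS) in which each analysis group has its own residual variance,
  estimated by iterating empirical per-group variances and per-sample
  weights ``1 / sigma2_group`` to convergence.

Plus the Wald test for a dosage column under either model, the
fully-adjusted two-stage rank-normalization of the trait, and per-group
analysis combined by inverse-variance fixed-effects meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CohortTable",
    "Design",
    "ModelFit",
    "AssocResult",
    "fit_homogeneous",
    "fit_stratified",
    "empirical_group_variances",
    "wald_test",
    "two_stage_rank_normalize",
    "per_group_meta",
]

MODEL_HOMOGENEOUS = "homogeneous"
MODEL_STRATIFIED = "stratified"

#: group variances below this are treated as collapsed (degenerate)
DEGENERATE_VARIANCE = 1e-12


@dataclass(frozen=True)
class Design:
    """Mean-model specification shared by all fits.

    ``covariates`` are numeric column names (e.g. a genetic PC);
    ``group_intercepts`` replaces the single intercept with one indicator
    per analysis group, absorbing between-group mean differences.
    """

    covariates: tuple[str, ...] = ()
    group_intercepts: bool = True


@dataclass
class CohortTable:
    """Per-sample analysis table.

    ``data`` must contain ``sample_id``, ``group_id`` and the trait column
    ``y``; covariates and genotype-dosage columns are additional numeric
    columns. Dosages must lie in [0, 2].
    """

    data: pd.DataFrame
    dosage_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"sample_id", "group_id", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing required columns: {sorted(missing)}")
        if self.data["y"].isna().any() or self.data["group_id"].isna().any():
            raise ValueError("missing trait or group_id values are not allowed")
        for col in self.dosage_cols:
            d = self.data[col].to_numpy(dtype=float)
            finite = d[np.isfinite(d)]
            if finite.size and (finite.min() < 0 or finite.max() > 2):
                raise ValueError(f"dosage column {col!r} has values outside [0, 2]")

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group_id"]))

    def group_sizes(self) -> pd.Series:
        return self.data.groupby("group_id", sort=False).size()


@dataclass
class ModelFit:
    """Result of a homogeneous or stratified variance-model fit."""

    coefficients: pd.Series
    residuals: pd.Series
    model_kind: str
    design: Design
    sigma2: Optional[float] = None
    group_variances: Optional[pd.Series] = None
    n_iterations: int = 0
    converged: bool = True
    cov_params: Optional[pd.DataFrame] = field(default=None, repr=False)
    variance_trace: Optional[list[pd.Series]] = field(default=None, repr=False)


@dataclass(frozen=True)
class AssocResult:
    """Single-variant association summary under one model."""

    variant_id: str
    beta: float
    se: float
    chi2: float
    p: float
    model: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"standard error must be > 0, got {self.se}")


def build_design_matrix(
    table: CohortTable, design: Design, variant: Optional[str] = None
) -> pd.DataFrame:
    """Assemble the regression design: dosage first, then intercept block,
    then covariates (dosage first so the genotype coefficient leads)."""
    df = table.data
    cols: dict[str, np.ndarray] = {}
    if variant is not None:
        cols[variant] = df[variant].to_numpy(dtype=float)
    if design.group_intercepts:
        for gid in table.groups:
            cols[f"intercept[{gid}]"] = (df["group_id"] == gid).to_numpy(dtype=float)
    else:
        cols["intercept"] = np.ones(len(df))
    for cov in design.covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate column {cov!r} not in cohort table")
        cols[cov] = df[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify an offending column by greedy elimination
        keep: list[int] = []
        bad: list[str] = []
        for j in range(arr.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(arr[:, trial]) == len(trial):
                keep = trial
            else:
                bad.append(X.columns[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_homogeneous(
    table: CohortTable, design: Design, variant: Optional[str] = None
) -> ModelFit:
    """Ordinary least squares with one shared residual variance.

    The shared variance is the standard df-corrected estimate
    ``RSS / (n - p)``; per-group empirical variances are available via
    :func:`empirical_group_variances`.
    """
    X = build_design_matrix(table, design, variant)
    if len(table.data) <= X.shape[1]:
        raise ValueError("need more samples than parameters")
    _check_full_rank(X)
    y = table.data["y"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return ModelFit(
        coefficients=res.params,
        residuals=pd.Series(res.resid, index=table.data.index),
        model_kind=MODEL_HOMOGENEOUS,
        design=design,
        sigma2=float(res.scale),
        cov_params=res.cov_params(),
    )


def empirical_group_variances(fit: ModelFit, table: CohortTable) -> pd.Series:
    """Per-group mean of squared residuals, no degrees-of-freedom correction.

    This is the empirical-variance estimator used to feed both the FGLS
    reweighting and the per-replicate lambda_vs evaluation.
    """
    resid = fit.residuals
    grouped = (resid**2).groupby(table.data["group_id"], sort=False)
    sizes = grouped.size()
    if (sizes == 0).any():
        raise ValueError("every analysis group must be non-empty")
    v = grouped.mean()
    if (v <= DEGENERATE_VARIANCE).any():
        degenerate = list(v.index[v <= DEGENERATE_VARIANCE])
        warnings.warn(
            f"degenerate (near-zero) residual variance in groups: {degenerate}",
            RuntimeWarning,
            stacklevel=2,
        )
    return v.reindex(pd.unique(table.data["group_id"]))


def fit_stratified(
    table: CohortTable,
    design: Design,
    variant: Optional[str] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> ModelFit:
    """Feasible GLS with one residual variance per analysis group.

    Starts from the homogeneous fit, then alternates (i) per-group
    empirical variances of the raw residuals and (ii) weighted least
    squares with per-sample weights ``1 / sigma2_group``, until the
    largest relative change in any group variance drops below ``tol``
    or ``max_iter`` is reached (``converged`` flags which).
    """
    sizes = table.group_sizes()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise ValueError(f"stratified fit needs >= 2 samples per group: {small}")

    fit = fit_homogeneous(table, design, variant)
    v = empirical_group_variances(fit, table)
    trace = [v.copy()]
    X = build_design_matrix(table, design, variant)
    y = table.data["y"].to_numpy(dtype=float)
    gid = table.data["group_id"]

    converged = False
    n_iter = 0
    res = None
    for n_iter in range(1, max_iter + 1):
        if (v <= DEGENERATE_VARIANCE).any():
            warnings.warn(
                "group variance collapsed toward zero; stopping FGLS iteration",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        w = 1.0 / v.loc[gid].to_numpy(dtype=float)
        res = sm.WLS(y, X, weights=w).fit()
        resid = pd.Series(y - res.fittedvalues, index=table.data.index)
        v_new = (resid**2).groupby(gid, sort=False).mean().reindex(v.index)
        rel_change = float(np.max(np.abs(v_new / v - 1.0)))
        v = v_new
        trace.append(v.copy())
        if rel_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"stratified variance fit did not converge in {n_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    if res is None:  # collapsed before the first WLS pass
        res_fit = fit
        res_fit.model_kind = MODEL_STRATIFIED
        res_fit.group_variances = v
        res_fit.converged = False
        return res_fit
    return ModelFit(
        coefficients=res.params,
        residuals=pd.Series(y - res.fittedvalues, index=table.data.index),
        model_kind=MODEL_STRATIFIED,
        design=design,
        group_variances=v,
        n_iterations=n_iter,
        converged=converged,
        cov_params=res.cov_params(),
        variance_trace=trace,
    )


def wald_test(fit: ModelFit, table: CohortTable, variant: str) -> AssocResult:
    """Wald test of a dosage column under the fit's model kind.

    Re-runs the fitting procedure (OLS, or the full FGLS iteration) with
    the variant included in the mean model; ``chi2 = (beta / se)^2`` is
    referred to the chi-square(1) upper tail.
    """
    dosage = table.data[variant].to_numpy(dtype=float)
    if np.allclose(dosage.var(), 0.0):
        raise ValueError(f"variant {variant!r} is monomorphic")
    if fit.model_kind == MODEL_STRATIFIED:
        full = fit_stratified(table, fit.design, variant)
    else:
        full = fit_homogeneous(table, fit.design, variant)
    beta = float(full.coefficients[variant])
    se = float(np.sqrt(full.cov_params.loc[variant, variant]))
    chi2 = (beta / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return AssocResult(
        variant_id=variant,
        beta=beta,
        se=se,
        chi2=chi2,
        p=max(p, np.nextafter(0, 1)),
        model=full.model_kind,
    )


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Maps value of rank r (ties -> average rank) to the normal quantile at
    ``(r - 3/8) / (n + 1/4)``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def two_stage_rank_normalize(table: CohortTable, design: Design) -> CohortTable:
    """Fully-adjusted two-stage rank-normalization of the trait.

    Stage 1 fits the covariate-only (null) model; its residuals are
    rank-normalized and become the new trait, so downstream association
    fits re-adjust for the same covariates on the transformed scale.
    """
    if len(table.data) < 3:
        raise ValueError("two-stage rank normalization needs at least 3 samples")
    null_fit = fit_homogeneous(table, design)
    new_y = rank_normalize(null_fit.residuals.to_numpy())
    data = table.data.copy()
    data["y"] = new_y
    return replace(table, data=data)


def per_group_meta(
    table: CohortTable, design: Design, variant: str
) -> tuple[AssocResult, list[str]]:
    """Per-group association fits combined by fixed-effects meta-analysis.

    Each analysis group is fit separately (its own intercept, covariates,
    residual variance — complete stratification), then effects are pooled
    with inverse-variance weights ``1 / se^2``. Groups where the variant
    is monomorphic are skipped and returned alongside the result.
    """
    betas: list[float] = []
    ses: list[float] = []
    skipped: list[str] = []
    sub_design = Design(covariates=design.covariates, group_intercepts=False)
    for gid in table.groups:
        sub = table.data[table.data["group_id"] == gid]
        if np.allclose(sub[variant].to_numpy(dtype=float).var(), 0.0):
            skipped.append(gid)
            continue
        sub_table = CohortTable(sub, dosage_cols=table.dosage_cols)
        res = wald_test(fit_homogeneous(sub_table, sub_design), sub_table, variant)
        if not np.isfinite(res.se) or res.se <= 0:
            raise ValueError(f"degenerate standard error in group {gid!r}")
        betas.append(res.beta)
        ses.append(res.se)
    if not betas:
        raise ValueError(f"variant {variant!r} is monomorphic in every group")
    w = 1.0 / np.asarray(ses) ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    chi2 = (beta / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return (
        AssocResult(
            variant_id=variant,
            beta=beta,
            se=se,
            chi2=chi2,
            p=max(p, np.nextafter(0, 1)),
            model="per_group_meta",
        ),
        skipped,
    )
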