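"""Variant-specific inflation factors from group-level summaries.

A variant analysed in a pooled sample of M analysis groups has a
large-sample Wald-statistic inflation factor ``lambda_vs`` that depends
only on each group's sample size ``n_m``, coded-allele frequency ``p_m``
and phenotypic variance ``sigma2_m``. The factor is the ratio of the true
(heterogeneous-variance, sandwich) sampling variance of the genotype
coefficient to the variance assumed by a single-residual-variance model,
both evaluated in the Hardy-Weinberg large-sample limit of the group-
intercept design:

    B = X' P X,  A = X' P V X
    lambda_vs = [B^-1 A B^-1]_gg / ([B^-1]_gg * tr(PV))

where X stacks the genotype column (0, 1, 2 per group) next to group
intercepts, P holds genotype-by-group HWE cell probabilities, and V the
per-group phenotypic variances. ``lambda_vs`` is 1 exactly when all
groups share the same allele frequency or the same variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "HweLimitMatrices",
    "InflationFactor",
    "build_hwe_matrices",
    "lambda_vs",
    "lambda_vs_two_group_batch",
    "lambda_vs_two_study_oracle",
    "lambda_vs_table",
    "categorize",
]

#: condition-number estimate above which the design limit B is declared singular
SINGULAR_COND_THRESHOLD = 1e12

#: lambda_vs category thresholds: below lower -> Deflated, above upper -> Inflated
DEFAULT_LOWER = 0.99
DEFAULT_UPPER = 1.01

CATEGORY_DEFLATED = "Deflated"
CATEGORY_NONE = "ApproxNone"
CATEGORY_INFLATED = "Inflated"


@dataclass(frozen=True)
class GroupSummary:
    """One analysis group's contribution to the lambda_vs computation.

    Parameters
    ----------
    group_id
        Unique label of the analysis group (study, or study x ethnicity).
    n
        Number of individuals in the group.
    p
        Coded (counted) allele frequency of the variant in this group, so
        the HWE cell probabilities for dosages (0, 1, 2) are
        ``((1-p)^2, 2p(1-p), p^2)``. lambda_vs is invariant to flipping
        the coded allele simultaneously in all groups.
    sigma2
        Phenotypic (total outcome) variance of the group, in squared trait
        units.
    """

    group_id: str
    n: int
    p: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.group_id!r}: n must be >= 1, got {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(
                f"group {self.group_id!r}: allele frequency must be in [0, 1], got {self.p}"
            )
        if not self.sigma2 > 0:
            raise ValueError(
                f"group {self.group_id!r}: sigma2 must be > 0, got {self.sigma2}"
            )


@dataclass(frozen=True)
class HweLimitMatrices:
    """Large-sample HWE limits of the group-intercept design moments.

    ``X`` is the 3M x (M+1) reduced design (genotype column then group
    intercepts), ``P`` the diagonal of genotype-by-group population
    proportions (sums to 1), ``V`` the diagonal of per-cell outcome
    variances, and ``B = X'PX``, ``A = X'PVX`` are the limits of the
    scaled ``W'W`` and ``W'VW`` moment matrices of the full design.
    """

    X: np.ndarray
    P: np.ndarray
    V: np.ndarray
    B: np.ndarray
    A: np.ndarray


@dataclass(frozen=True)
class InflationFactor:
    """Per-variant lambda_vs with its inflation category."""

    variant_id: str
    lambda_vs: float
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.lambda_vs > 0:
            raise ValueError(f"lambda_vs must be > 0, got {self.lambda_vs}")


def _validate_groups(groups: Sequence[GroupSummary]) -> None:
    if len(groups) == 0:
        raise ValueError("at least one analysis group is required")
    seen = set()
    for g in groups:
        if g.group_id in seen:
            raise ValueError(f"duplicate group_id {g.group_id!r}")
        seen.add(g.group_id)


def build_hwe_matrices(groups: Sequence[GroupSummary]) -> HweLimitMatrices:
    """Construct the HWE large-sample limit matrices X, P, V, B, A.

    Each group contributes three rows (dosages 0, 1, 2); the cell
    probability of dosage k in group m is the group's sample fraction
    ``n_m / n`` times the HWE trinomial probability for its coded-allele
    frequency, and its outcome variance is the group's ``sigma2``.
    """
    _validate_groups(groups)
    m = len(groups)
    n_total = float(sum(g.n for g in groups))

    X = np.zeros((3 * m, m + 1))
    p_diag = np.zeros(3 * m)
    v_diag = np.zeros(3 * m)
    for j, g in enumerate(groups):
        rows = slice(3 * j, 3 * j + 3)
        X[rows, 0] = (0.0, 1.0, 2.0)
        X[rows, 1 + j] = 1.0
        frac = g.n / n_total
        q = 1.0 - g.p
        p_diag[rows] = (frac * q * q, frac * 2.0 * g.p * q, frac * g.p * g.p)
        v_diag[rows] = g.sigma2

    P = np.diag(p_diag)
    V = np.diag(v_diag)
    B = X.T @ (p_diag[:, None] * X)
    A = X.T @ ((p_diag * v_diag)[:, None] * X)
    return HweLimitMatrices(X=X, P=P, V=V, B=B, A=A)


def lambda_vs(groups: Sequence[GroupSummary]) -> float:
    """Variant-specific inflation factor via the matrix-limit algorithm.

    Returns the ratio of the leading (genotype-coefficient) entry of
    ``B^-1 A B^-1`` (true sampling variance under heterogeneous group
    variances) to the leading entry of ``B^-1 * tr(PV)`` (variance assumed
    by the homogeneous-variance model). Values above 1 predict inflation
    of the variant's Wald chi-square under the homogeneous model, values
    below 1 predict deflation.

    Raises
    ------
    np.linalg.LinAlgError
        If the genotype column is constant in the pooled limit (every
        group has p in {0, 1}), making the design limit singular.
    """
    mats = build_hwe_matrices(groups)
    B, A = mats.B, mats.A
    if np.linalg.cond(B) > SINGULAR_COND_THRESHOLD:
        raise np.linalg.LinAlgError(
            "design limit matrix B is singular: genotype column is constant "
            "in the pooled HWE limit (all group frequencies at 0 or 1)"
        )
    e0 = np.zeros(B.shape[0])
    e0[0] = 1.0
    u = np.linalg.solve(B, e0)  # first column of B^-1 (B symmetric)
    var_het = float(u @ A @ u)
    trace_pv = float(np.trace(mats.P @ mats.V))
    var_hom = float(u[0]) * trace_pv
    return var_het / var_hom


def lambda_vs_two_group_batch(
    n1: np.ndarray,
    n2: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    sigma2_1: np.ndarray,
    sigma2_2: np.ndarray,
) -> np.ndarray:
    """Vectorized two-group matrix-limit lambda_vs.

    Builds the 3x3 moment limits B and A of the two-group design for each
    element of the broadcast inputs and solves them in a single batched
    call; identical in exact arithmetic to :func:`lambda_vs` at M = 2.
    Used by the simulation module to evaluate lambda_vs per replicate.
    """
    n1, n2, p1, p2, s1, s2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (n1, n2, p1, p2, sigma2_1, sigma2_2))
    )
    n = n1 + n2
    f1, f2 = n1 / n, n2 / n
    # HWE first and second moments of dosage per group
    eg1, eg2 = 2.0 * p1, 2.0 * p2
    eg1_sq = 2.0 * p1 * (1.0 - p1) + eg1**2
    eg2_sq = 2.0 * p2 * (1.0 - p2) + eg2**2

    shape = n1.shape
    B = np.zeros(shape + (3, 3))
    B[..., 0, 0] = f1 * eg1_sq + f2 * eg2_sq
    B[..., 0, 1] = B[..., 1, 0] = f1 * eg1
    B[..., 0, 2] = B[..., 2, 0] = f2 * eg2
    B[..., 1, 1] = f1
    B[..., 2, 2] = f2

    A = np.zeros(shape + (3, 3))
    A[..., 0, 0] = f1 * s1 * eg1_sq + f2 * s2 * eg2_sq
    A[..., 0, 1] = A[..., 1, 0] = f1 * s1 * eg1
    A[..., 0, 2] = A[..., 2, 0] = f2 * s2 * eg2
    A[..., 1, 1] = f1 * s1
    A[..., 2, 2] = f2 * s2

    e0 = np.zeros(shape + (3,))
    e0[..., 0] = 1.0
    u = np.linalg.solve(B, e0[..., None])[..., 0]
    var_het = np.einsum("...i,...ij,...j->...", u, A, u)
    var_hom = u[..., 0] * (f1 * s1 + f2 * s2)
    return var_het / var_hom


def lambda_vs_two_study_oracle(g1: GroupSummary, g2: GroupSummary) -> float:
    """Closed-form two-study lambda_vs.

    With genotype-information weights ``w_m = n_m p_m (1 - p_m)``, the
    heterogeneous-variance sampling variance of the slope is proportional
    to ``sum(w_m sigma2_m) / (sum w_m)^2`` while the homogeneous model
    assumes ``sigma_bar^2 / sum(w_m)`` with the pooled variance
    ``sigma_bar^2 = (n1 sigma2_1 + n2 sigma2_2) / n``, giving

        lambda_vs = sum(w_m sigma2_m) / (sigma_bar^2 * sum(w_m)).

    Serves as the algebra-independent oracle for :func:`lambda_vs` at M=2.
    """
    w1 = g1.n * g1.p * (1.0 - g1.p)
    w2 = g2.n * g2.p * (1.0 - g2.p)
    w_sum = w1 + w2
    if w_sum <= 0:
        raise np.linalg.LinAlgError(
            "genotype column constant in both groups (p in {0, 1}); "
            "lambda_vs is undefined"
        )
    sigma_bar2 = (g1.n * g1.sigma2 + g2.n * g2.sigma2) / (g1.n + g2.n)
    return (w1 * g1.sigma2 + w2 * g2.sigma2) / (sigma_bar2 * w_sum)


def categorize(
    lam: float, lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER
) -> str:
    """Assign the Deflated / ApproxNone / Inflated category.

    Boundary values (exactly ``lower`` or ``upper``) are ApproxNone.
    """
    if not lam > 0:
        raise ValueError(f"lambda_vs must be > 0, got {lam}")
    if not lower < upper:
        raise ValueError(f"thresholds must satisfy lower < upper, got {lower}, {upper}")
    if lam < lower:
        return CATEGORY_DEFLATED
    if lam > upper:
        return CATEGORY_INFLATED
    return CATEGORY_NONE


def lambda_vs_table(
    groups: Sequence[GroupSummary],
    freqs: pd.DataFrame,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> pd.DataFrame:
    """Compute lambda_vs and category for a table of variants.

    Parameters
    ----------
    groups
        Group roster supplying ``n`` and ``sigma2``; the per-variant
        frequencies in ``freqs`` override each group's ``p``.
    freqs
        DataFrame with a ``variant_id`` column and one coded-allele
        frequency column per ``group_id``.

    Returns
    -------
    DataFrame with columns ``variant_id``, ``lambda_vs``, ``category``.
    """
    _validate_groups(groups)
    missing = [g.group_id for g in groups if g.group_id not in freqs.columns]
    if missing:
        raise ValueError(f"frequency table lacks columns for groups: {missing}")

    records = []
    for row in freqs.itertuples(index=False):
        row_d = row._asdict()
        vgroups = [
            GroupSummary(g.group_id, g.n, float(row_d[g.group_id]), g.sigma2)
            for g in groups
        ]
        lam = lambda_vs(vgroups)
        records.append(
            {
                "variant_id": row_d["variant_id"],
                "lambda_vs": lam,
                "category": categorize(lam, lower, upper),
            }
        )
    return pd.DataFrame.from_records(records, columns=["variant_id", "lambda_vs", "category"])


def make_inflation_factors(
    table: pd.DataFrame,
) -> list[InflationFactor]:
    """Convert a lambda table (as from :func:`lambda_vs_table`) to records."""
    return [
        InflationFactor(str(r.variant_id), float(r.lambda_vs), str(r.category))
        for r in table.itertuples(index=False)
    ]
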