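"""Genomic-control and QQ diagnostics for variance stratification.

The genomic-control inflation factor of a variant set is the median of
its chi-square(1) Wald statistics over the theoretical null median
(~0.4549). Because variance stratification inflates some variants and
deflates others, the overall lambda_gc can look well calibrated while
category-level QQ series (variants grouped by their predicted lambda_vs
category) reveal the miscalibration — the masking phenomenon. This
module computes lambda_gc, its null sampling band, category-stratified
QQ series, and the MAF-by-lambda_vs contingency summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from varstrat.inflation import (
    CATEGORY_DEFLATED,
    CATEGORY_INFLATED,
    CATEGORY_NONE,
)

__all__ = [
    "QqSeries",
    "genomic_control_lambda",
    "null_lambda_band",
    "stratified_qq",
    "tabulate_by_maf",
    "DEFAULT_LAMBDA_BINS",
]

logger = logging.getLogger(__name__)

CATEGORY_ALL = "All"

#: reporting bins for lambda_vs in the MAF contingency summary
DEFAULT_LAMBDA_BINS = (0.0, 0.9, 0.95, 0.99, 1.01, 1.05, 1.1, np.inf)

DEFAULT_MAF_BINS = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5)


@dataclass(frozen=True)
class QqSeries:
    """One QQ curve: paired expected / observed -log10 p-values, ordered
    from the most significant (smallest p) to the least."""

    category: str
    expected: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        if self.expected.shape != self.observed.shape:
            raise ValueError("expected and observed must have equal length")


def genomic_control_lambda(chi2: Union[Sequence[float], np.ndarray]) -> float:
    """lambda_gc = median observed chi-square(1) / theoretical null median."""
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("cannot compute lambda_gc of an empty statistic set")
    if (chi2 < 0).any():
        raise ValueError("chi-square statistics must be non-negative")
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def null_lambda_band(
    n_stats: int = 10000,
    n_sets: int = 1000,
    alpha_low: float = 0.025,
    alpha_high: float = 0.975,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Sampling band of lambda_gc under the null.

    Simulates ``n_sets`` independent sets of ``n_stats`` chi-square(1)
    statistics, computes each set's lambda_gc, and returns the
    (alpha_low, alpha_high) quantiles — the spread attributable to pure
    sampling noise at the given set size.
    """
    if n_sets < 100:
        raise ValueError("n_sets < 100 gives unusable quantile estimates")
    rng = np.random.default_rng(seed)
    med = stats.chi2.ppf(0.5, df=1)
    # chunk the sets so memory stays modest at large n_stats
    lambdas = np.empty(n_sets)
    chunk = max(1, int(2e7 / n_stats))
    for start in range(0, n_sets, chunk):
        stop = min(start + chunk, n_sets)
        draws = rng.chisquare(1, size=(stop - start, n_stats))
        lambdas[start:stop] = np.median(draws, axis=1) / med
    return (
        float(np.quantile(lambdas, alpha_low)),
        float(np.quantile(lambdas, alpha_high)),
    )


def _qq_pair(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = p.size
    observed = -np.log10(np.sort(p))  # ascending p: most significant first
    ranks = np.arange(1, k + 1)
    expected = -np.log10((ranks - 0.5) / k)
    return expected, observed


def stratified_qq(
    pvalues: pd.DataFrame,
    categories: Sequence[str] = (CATEGORY_DEFLATED, CATEGORY_NONE, CATEGORY_INFLATED),
) -> list[QqSeries]:
    """Category-stratified QQ series plus the pooled "All" series.

    ``pvalues`` needs columns ``p`` and ``category``. Expected quantiles
    use the (i - 0.5) / k plotting positions within each category of size
    k. Empty categories are omitted with a log note.
    """
    p = pvalues["p"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    series: list[QqSeries] = []
    for cat in categories:
        mask = (pvalues["category"] == cat).to_numpy()
        if not mask.any():
            logger.info("category %r is empty; QQ series omitted", cat)
            continue
        exp, obs = _qq_pair(p[mask])
        series.append(QqSeries(cat, exp, obs))
    exp, obs = _qq_pair(p)
    series.append(QqSeries(CATEGORY_ALL, exp, obs))
    return series


def qq_to_frame(series: Sequence[QqSeries]) -> pd.DataFrame:
    """Tidy long-format table of QQ series (category, expected, observed)."""
    frames = [
        pd.DataFrame(
            {"category": s.category, "expected": s.expected, "observed": s.observed}
        )
        for s in series
    ]
    return pd.concat(frames, ignore_index=True)


def tabulate_by_maf(
    lambdas: pd.DataFrame,
    mafs: pd.Series,
    maf_bins: Sequence[float] = DEFAULT_MAF_BINS,
    lambda_bins: Sequence[float] = DEFAULT_LAMBDA_BINS,
) -> pd.DataFrame:
    """Counts and row-percentages of variants per MAF bin x lambda_vs bin.

    ``lambdas`` needs columns ``variant_id`` and ``lambda_vs``; ``mafs``
    is indexed by variant_id with pooled minor-allele frequencies in
    (0, 0.5]. Variants whose MAF falls outside the bins are reported and
    excluded.
    """
    maf = mafs.reindex(lambdas["variant_id"]).to_numpy(dtype=float)
    lam = lambdas["lambda_vs"].to_numpy(dtype=float)
    maf_cat = pd.cut(maf, bins=list(maf_bins))
    lam_cat = pd.cut(lam, bins=list(lambda_bins))
    dropped = int(pd.isna(maf_cat).sum())
    if dropped:
        logger.warning("%d variants outside the MAF bins were excluded", dropped)
    table = pd.crosstab(maf_cat, lam_cat, dropna=False)
    table.index.name = "maf_bin"
    table.columns.name = "lambda_bin"
    pct = table.div(table.sum(axis=1).replace(0, np.nan), axis=0) * 100.0
    counts = table.copy()
    counts.columns = [f"n {c}" for c in counts.columns]
    pct.columns = [f"% {c}" for c in pct.columns]
    return pd.concat([counts, pct], axis=1)
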