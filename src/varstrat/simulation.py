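"""Two-study null simulations validating the variant-specific inflation factor.

Each replicate draws a two-study sample: a genetic PC theta ~ N(mu_study, 1)
with study means balancing to zero overall, independent biallelic dosages
g ~ Binomial(2, p_study), and a trait

    y = intercept_study + pc_effect * theta + eps

with the genotype absent from the mean model (strict null). The error
variance is sigma2_study + sigma2_g ("constant" mode) or
sigma2_study + theta^2 * sigma2_g ("pc_scaled" mode, variance driven by
the PC). Per replicate both the homogeneous-variance and the
stratified-variance model are fit with the genotype included; observed
genomic-control inflation lambda_gc = median(chi2) / median(chi2_1) is
compared with the mean of per-replicate lambda_vs values computed from
estimated variances and observed study allele frequencies.

The canonical study grid crosses n in {1000, 5000}, error and genetic
variances in {1, 2}, frequencies in {0.01, 0.05, 0.5} and both variance
modes: 576 settings, 10,000 replicates each.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from varstrat.inflation import lambda_vs_two_group_batch
from varstrat.models import CohortTable

__all__ = [
    "SimSetting",
    "SettingResult",
    "enumerate_grid",
    "simulate_pc",
    "simulate_genotypes",
    "simulate_phenotype",
    "run_setting",
    "chi2_1_median",
]

logger = logging.getLogger(__name__)

VARIANCE_MODES = ("constant", "pc_scaled")

_GRID_N = (1000, 5000)
_GRID_SIGMA2 = (1.0, 2.0)
_GRID_P = (0.01, 0.05, 0.5)


def chi2_1_median() -> float:
    """Theoretical median of the chi-square(1) distribution (~0.4549)."""
    return float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class SimSetting:
    """One cell of the simulation grid.

    Intercepts (1 and 2), the PC effect (1) and the study-1 PC mean (2)
    are fixed across the whole study; the remaining parameters vary.
    """

    n1: int
    n2: int
    sigma2_1: float
    sigma2_2: float
    sigma2_g: float
    p1: float
    p2: float
    variance_mode: str
    intercept1: float = 1.0
    intercept2: float = 2.0
    pc_effect: float = 1.0
    pc_mean1: float = 2.0

    def __post_init__(self) -> None:
        if self.variance_mode not in VARIANCE_MODES:
            raise ValueError(
                f"variance_mode must be one of {VARIANCE_MODES}, got {self.variance_mode!r}"
            )
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("study sizes must be >= 1")
        for name in ("sigma2_1", "sigma2_2", "sigma2_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p1", "p2"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @property
    def pc_mean2(self) -> float:
        """Study-2 PC mean balancing the pooled expectation to zero."""
        return -self.n1 * self.pc_mean1 / self.n2


@dataclass(frozen=True)
class SettingResult:
    """Observed inflation and mean estimated lambda_vs for one setting."""

    setting: SimSetting
    n_reps: int
    lambda_gc_homogeneous: float
    lambda_gc_stratified: float
    mean_lambda_vs_empirical: float
    mean_lambda_vs_stratified: float
    seed: int
    n_redraws: int = 0

    @property
    def mean_lambda_vs(self) -> dict[str, float]:
        return {
            "empirical-homogeneous": self.mean_lambda_vs_empirical,
            "stratified": self.mean_lambda_vs_stratified,
        }


def enumerate_grid() -> list[SimSetting]:
    """The full 576-setting Cartesian grid, in deterministic order."""
    settings = [
        SimSetting(n1, n2, s1, s2, sg, p1, p2, mode)
        for n1, n2, s1, s2, sg, p1, p2, mode in itertools.product(
            _GRID_N, _GRID_N, _GRID_SIGMA2, _GRID_SIGMA2, _GRID_SIGMA2,
            _GRID_P, _GRID_P, VARIANCE_MODES,
        )
    ]
    return settings


def demo_stratified_settings() -> list[SimSetting]:
    """Twelve grid settings exhibiting variance stratification.

    All have p1 != p2 and sigma2_1 != sigma2_2 (so lambda_vs != 1),
    spanning inflated and deflated regimes, both genetic-variance levels
    and both variance modes, at n1 = n2 = 1000. Used for the scaled-down
    validation of the lambda_vs / lambda_gc diagonal.
    """
    combos = [
        (2.0, 1.0, 1.0, 0.01, 0.5, "constant"),
        (2.0, 1.0, 1.0, 0.5, 0.01, "constant"),
        (2.0, 1.0, 1.0, 0.05, 0.5, "constant"),
        (2.0, 1.0, 1.0, 0.5, 0.05, "constant"),
        (1.0, 2.0, 1.0, 0.01, 0.5, "constant"),
        (1.0, 2.0, 1.0, 0.05, 0.5, "constant"),
        (2.0, 1.0, 2.0, 0.01, 0.5, "constant"),
        (1.0, 2.0, 2.0, 0.5, 0.01, "constant"),
        (2.0, 1.0, 1.0, 0.01, 0.5, "pc_scaled"),
        (2.0, 1.0, 1.0, 0.5, 0.01, "pc_scaled"),
        (1.0, 2.0, 1.0, 0.05, 0.5, "pc_scaled"),
        (1.0, 2.0, 1.0, 0.5, 0.05, "pc_scaled"),
    ]
    return [
        SimSetting(1000, 1000, s1, s2, sg, p1, p2, mode)
        for s1, s2, sg, p1, p2, mode in combos
    ]


def _as_rng(seed: Union[int, np.random.Generator, np.random.SeedSequence]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_pc(
    n1: int,
    n2: int,
    mu1: float = 2.0,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Draw the PC: N(mu1, 1) in study 1, N(mu2, 1) in study 2 with
    mu2 = -n1 mu1 / n2 so the pooled expected mean is zero."""
    rng = _as_rng(seed)
    mu2 = -n1 * mu1 / n2
    return np.concatenate([rng.normal(mu1, 1.0, n1), rng.normal(mu2, 1.0, n2)])


def simulate_genotypes(
    p: float, n: int, seed: Union[int, np.random.Generator, None] = None
) -> np.ndarray:
    """i.i.d. Binomial(2, p) dosages for one study."""
    if not 0 < p < 1:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    rng = _as_rng(seed)
    return rng.binomial(2, p, size=n).astype(float)


def _error_sd(setting: SimSetting, pc: np.ndarray) -> np.ndarray:
    n1 = setting.n1
    var = np.empty(pc.size)
    var[:n1] = setting.sigma2_1
    var[n1:] = setting.sigma2_2
    if setting.variance_mode == "constant":
        var += setting.sigma2_g
    else:
        var += pc**2 * setting.sigma2_g
    return np.sqrt(var)


def simulate_phenotype(
    setting: SimSetting,
    pc: np.ndarray,
    seed: Union[int, np.random.Generator, None] = None,
) -> CohortTable:
    """Trait under the strict null: study intercept + PC effect + noise.

    Returns a :class:`CohortTable` with columns sample_id, group_id, y, pc;
    genotypes are drawn separately because they never enter the mean model.
    """
    n = setting.n1 + setting.n2
    if pc.size != n:
        raise ValueError(f"pc length {pc.size} != n1 + n2 = {n}")
    rng = _as_rng(seed)
    mean = np.empty(n)
    mean[: setting.n1] = setting.intercept1
    mean[setting.n1 :] = setting.intercept2
    mean += setting.pc_effect * pc
    y = mean + rng.normal(0.0, _error_sd(setting, pc))
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group_id": ["study1"] * setting.n1 + ["study2"] * setting.n2,
            "y": y,
            "pc": pc,
        }
    )
    return CohortTable(df)


def _draw_replicate(
    setting: SimSetting, rng: np.random.Generator, max_redraws: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """One replicate's (pc, genotype, y); pooled-monomorphic variants are
    redrawn so every replicate contributes a testable variant."""
    n1, n2 = setting.n1, setting.n2
    pc = simulate_pc(n1, n2, setting.pc_mean1, rng)
    redraws = 0
    while True:
        g = np.concatenate(
            [simulate_genotypes(setting.p1, n1, rng), simulate_genotypes(setting.p2, n2, rng)]
        )
        if g.min() != g.max():
            break
        redraws += 1
        if redraws > max_redraws:
            raise RuntimeError("variant persistently monomorphic; check frequencies")
    mean = np.empty(n1 + n2)
    mean[:n1] = setting.intercept1
    mean[n1:] = setting.intercept2
    mean += setting.pc_effect * pc
    y = mean + rng.normal(0.0, _error_sd(setting, pc))
    return pc, g, y, redraws


def replicate_table(
    setting: SimSetting, seed: Union[int, np.random.SeedSequence]
) -> CohortTable:
    """Materialize a single replicate as a CohortTable with dosage column 'g'
    (same draw order as the batched kernel in :func:`run_setting`)."""
    rng = _as_rng(seed)
    pc, g, y, _ = _draw_replicate(setting, rng)
    n = setting.n1 + setting.n2
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group_id": ["study1"] * setting.n1 + ["study2"] * setting.n2,
            "y": y,
            "pc": pc,
            "g": g,
        }
    )
    return CohortTable(df, dosage_cols=("g",))


def _batched_fits(
    X: np.ndarray, y: np.ndarray, n1: int, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Homogeneous OLS and stratified FGLS for a batch of replicates.

    X has shape (reps, n, k) with the genotype in column 0, y shape
    (reps, n). Returns (chi2_hom, chi2_strat, v_emp, v_strat) where the
    variance arrays have shape (reps, 2) in study order. Implements the
    same normal-equation algebra as the statsmodels-backed single fits.
    """
    reps, n, k = X.shape
    n2 = n - n1
    X1, X2 = X[:, :n1, :], X[:, n1:, :]
    y1, y2 = y[:, :n1], y[:, n1:]

    G1 = np.einsum("rni,rnj->rij", X1, X1)
    G2 = np.einsum("rni,rnj->rij", X2, X2)
    b1 = np.einsum("rni,rn->ri", X1, y1)
    b2 = np.einsum("rni,rn->ri", X2, y2)
    yy1 = np.einsum("rn,rn->r", y1, y1)
    yy2 = np.einsum("rn,rn->r", y2, y2)

    def group_rss(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q1 = np.einsum("ri,rij,rj->r", beta, G1, beta)
        q2 = np.einsum("ri,rij,rj->r", beta, G2, beta)
        r1 = yy1 - 2.0 * np.einsum("ri,ri->r", beta, b1) + q1
        r2 = yy2 - 2.0 * np.einsum("ri,ri->r", beta, b2) + q2
        return r1, r2

    e0 = np.zeros((reps, k))
    e0[:, 0] = 1.0

    # homogeneous OLS
    XtX = G1 + G2
    beta = np.linalg.solve(XtX, (b1 + b2)[..., None])[..., 0]
    rss1, rss2 = group_rss(beta)
    scale = (rss1 + rss2) / (n - k)
    inv00 = np.linalg.solve(XtX, e0[..., None])[:, 0, 0]
    chi2_hom = beta[:, 0] ** 2 / (scale * inv00)
    v_emp = np.stack([rss1 / n1, rss2 / n2], axis=1)

    # stratified FGLS: iterate empirical variances and weighted refits
    v = v_emp.copy()
    for _ in range(max_iter):
        M = G1 / v[:, 0, None, None] + G2 / v[:, 1, None, None]
        rhs = b1 / v[:, 0, None] + b2 / v[:, 1, None]
        beta_s = np.linalg.solve(M, rhs[..., None])[..., 0]
        rss1s, rss2s = group_rss(beta_s)
        v_new = np.stack([rss1s / n1, rss2s / n2], axis=1)
        rel = np.max(np.abs(v_new / v - 1.0))
        v_prev = v
        v = v_new
        if rel < tol:
            break
    w_rss = rss1s / v_prev[:, 0] + rss2s / v_prev[:, 1]
    inv00_w = np.linalg.solve(M, e0[..., None])[:, 0, 0]
    chi2_strat = beta_s[:, 0] ** 2 / ((w_rss / (n - k)) * inv00_w)
    return chi2_hom, chi2_strat, v_emp, v


def run_setting(
    setting: SimSetting,
    n_reps: int = 10000,
    seed: int = 0,
    chunk_size: Optional[int] = None,
) -> SettingResult:
    """Run one grid setting: fresh PC, genotypes and trait per replicate,
    Wald chi-squares under both models, and per-replicate lambda_vs from
    estimated variances and observed study allele frequencies.

    lambda_gc per model is median(chi2) over replicates divided by the
    chi-square(1) median; lambda_vs estimates are averaged across
    replicates, separately for the empirical (homogeneous-fit residual)
    and stratified (FGLS) variance estimators.
    """
    if n_reps < 100:
        raise ValueError("n_reps < 100 is statistically meaningless; refusing to run")
    n1, n2 = setting.n1, setting.n2
    n = n1 + n2
    k = 4  # genotype, two study intercepts, PC
    if chunk_size is None:
        chunk_size = max(50, int(2_000_000 / n))

    children = np.random.SeedSequence(seed).spawn(n_reps)
    chi2_hom = np.empty(n_reps)
    chi2_strat = np.empty(n_reps)
    lam_emp = np.empty(n_reps)
    lam_strat = np.empty(n_reps)
    total_redraws = 0

    intercepts = np.zeros((n, 2))
    intercepts[:n1, 0] = 1.0
    intercepts[n1:, 1] = 1.0

    for start in range(0, n_reps, chunk_size):
        stop = min(start + chunk_size, n_reps)
        c = stop - start
        X = np.empty((c, n, k))
        Y = np.empty((c, n))
        X[:, :, 1:3] = intercepts
        for i in range(c):
            rng = np.random.default_rng(children[start + i])
            pc, g, y, redraws = _draw_replicate(setting, rng)
            total_redraws += redraws
            X[i, :, 0] = g
            X[i, :, 3] = pc
            Y[i] = y
        ch, cs, v_emp, v_strat = _batched_fits(X, Y, n1)
        chi2_hom[start:stop] = ch
        chi2_strat[start:stop] = cs
        p1_hat = X[:, :n1, 0].mean(axis=1) / 2.0
        p2_hat = X[:, n1:, 0].mean(axis=1) / 2.0
        lam_emp[start:stop] = lambda_vs_two_group_batch(
            n1, n2, p1_hat, p2_hat, v_emp[:, 0], v_emp[:, 1]
        )
        lam_strat[start:stop] = lambda_vs_two_group_batch(
            n1, n2, p1_hat, p2_hat, v_strat[:, 0], v_strat[:, 1]
        )

    if total_redraws:
        logger.info(
            "setting %s: %d pooled-monomorphic redraws over %d replicates",
            setting, total_redraws, n_reps,
        )
    med = chi2_1_median()
    return SettingResult(
        setting=setting,
        n_reps=n_reps,
        lambda_gc_homogeneous=float(np.median(chi2_hom) / med),
        lambda_gc_stratified=float(np.median(chi2_strat) / med),
        mean_lambda_vs_empirical=float(lam_emp.mean()),
        mean_lambda_vs_stratified=float(lam_strat.mean()),
        seed=seed,
        n_redraws=total_redraws,
    )


def results_to_frame(results: Sequence[SettingResult]) -> pd.DataFrame:
    """Flatten SettingResults into a tidy table (one row per setting)."""
    rows = []
    for r in results:
        s = r.setting
        rows.append(
            {
                "n1": s.n1, "n2": s.n2,
                "sigma2_1": s.sigma2_1, "sigma2_2": s.sigma2_2,
                "sigma2_g": s.sigma2_g, "p1": s.p1, "p2": s.p2,
                "variance_mode": s.variance_mode,
                "n_reps": r.n_reps,
                "lambda_gc_homogeneous": r.lambda_gc_homogeneous,
                "lambda_gc_stratified": r.lambda_gc_stratified,
                "mean_lambda_vs_empirical": r.mean_lambda_vs_empirical,
                "mean_lambda_vs_stratified": r.mean_lambda_vs_stratified,
                "seed": r.seed,
                "n_redraws": r.n_redraws,
            }
        )
    return pd.DataFrame(rows)
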