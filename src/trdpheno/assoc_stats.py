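"""Statistical layer: prevalences, odds ratios, polygenic-score association,
liability-scale transformations and effect-comparison tests.

Liability-threshold model notation used throughout: for a binary trait with
population prevalence K, disease corresponds to a latent standard-normal
liability exceeding the threshold t = Phi^{-1}(1 - K); z = phi(t) is the
normal density at the threshold, and P is the case proportion in the
(possibly ascertained) analysis sample.  Observed-scale variance components
from 0/1 case-control data are mapped to the liability scale with the
ascertainment-corrected transformations of Lee et al. (h2: AJHG 2011;
polygenic-score R2: Genet Epidemiol 2012).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "LiabilityParams",
    "ContingencyTable2x2",
    "PrsModel",
    "PrsAssociationResult",
    "prevalence_percent",
    "odds_ratio",
    "prs_score",
    "prs_association",
    "select_best_threshold",
    "h2_observed_to_liability",
    "h2_liability_to_observed",
    "r2_observed_to_liability",
    "z_compare_effects",
    "p_from_z",
    "bonferroni_threshold",
    "measure_overlap",
    "allelic_sumstats",
    "DEFAULT_P_THRESHOLDS",
]

#: Default 11 polygenic-score p-value thresholds (P_T); configurable.
DEFAULT_P_THRESHOLDS: tuple[float, ...] = (
    5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0
)


# -- liability-threshold parameters ---------------------------------------


@dataclass(frozen=True)
class LiabilityParams:
    """Population prevalence K and sample case proportion P, with the derived
    liability threshold t = Phi^{-1}(1-K) and density z = phi(t).

    t and z are computed from K in the constructor and never stored stale.
    """

    prevalence_k: float
    case_proportion_p: float
    threshold_t: float = field(init=False)
    density_z: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_k < 1.0:
            raise ValueError(f"prevalence K must be in (0,1), got {self.prevalence_k}")
        if not 0.0 < self.case_proportion_p < 1.0:
            raise ValueError(
                f"case proportion P must be in (0,1), got {self.case_proportion_p}"
            )
        t = stats.norm.isf(self.prevalence_k)
        object.__setattr__(self, "threshold_t", t)
        object.__setattr__(self, "density_z", stats.norm.pdf(t))


def h2_observed_to_liability(h2_obs: float, params: LiabilityParams) -> float:
    """Transform an observed-scale case-control h2 to the liability scale.

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 * P(1-P)), the ascertainment
    corrected transformation for case-control samples with sample case
    proportion P and population prevalence K.
    """
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    k, p, z = params.prevalence_k, params.case_proportion_p, params.density_z
    return h2_obs * k * k * (1 - k) * (1 - k) / (z * z * p * (1 - p))


def h2_liability_to_observed(h2_liab: float, params: LiabilityParams) -> float:
    """Inverse of :func:`h2_observed_to_liability`."""
    if h2_liab < 0:
        raise ValueError("h2_liab must be non-negative")
    k, p, z = params.prevalence_k, params.case_proportion_p, params.density_z
    return h2_liab * z * z * p * (1 - p) / (k * k * (1 - k) * (1 - k))


def r2_observed_to_liability(r2_obs: float, params: LiabilityParams) -> float:
    """Liability-scale R2 of a polygenic score from the observed-scale
    (0/1 outcome) R2 in an ascertained case-control sample.

    Uses the Lee et al. (2012) correction: with m = z/K the mean liability of
    cases, C = K(1-K)/z^2 * K(1-K)/(P(1-P)) and
    theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t),

        R2_liab = C * R2_obs / (1 + C * theta * R2_obs).

    With no ascertainment (P = K) theta vanishes and the expression reduces
    to the simple K(1-K)/z^2 rescaling.
    """
    if not 0.0 <= r2_obs < 1.0:
        raise ValueError("r2_obs must be in [0, 1)")
    k, p = params.prevalence_k, params.case_proportion_p
    t, z = params.threshold_t, params.density_z
    m = z / k
    c = k * (1 - k) / (z * z) * k * (1 - k) / (p * (1 - p))
    d = m * (p - k) / (1 - k)
    theta = d * (d - t)
    return c * r2_obs / (1 + c * theta * r2_obs)


# -- simple epidemiological quantities ------------------------------------


def prevalence_percent(n_case: int, n_total: int) -> float:
    """Prevalence as a percentage, rounded to 2 decimal places."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_case <= n_total:
        raise ValueError("need 0 <= n_case <= n_total")
    return round(100.0 * n_case / n_total, 2)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b,c,d = exposed-case, exposed-noncase, unexposed-case,
    unexposed-noncase."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    continuity_corrected: bool


def odds_ratio(table: ContingencyTable2x2, conf_level: float = 0.95) -> OddsRatioResult:
    """Odds ratio ad/(bc) with a Woolf (log-normal) confidence interval.

    Zero cells trigger the Haldane-Anscombe correction (0.5 added to every
    cell), flagged in the output.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zcrit = stats.norm.isf((1 - conf_level) / 2)
    return OddsRatioResult(
        oddsratio=math.exp(log_or),
        ci_low=math.exp(log_or - zcrit * se),
        ci_high=math.exp(log_or + zcrit * se),
        log_or=log_or,
        se_log_or=se,
        continuity_corrected=corrected,
    )


# -- polygenic scoring and association ------------------------------------


@dataclass
class PrsModel:
    """Per-SNP weights and discovery p-values plus the P_T grid."""

    snp_weights: np.ndarray
    snp_pvalues: np.ndarray
    thresholds: Sequence[float] = DEFAULT_P_THRESHOLDS
    selected_threshold: float | None = None

    def __post_init__(self) -> None:
        self.snp_weights = np.asarray(self.snp_weights, dtype=float)
        self.snp_pvalues = np.asarray(self.snp_pvalues, dtype=float)
        if self.snp_weights.shape != self.snp_pvalues.shape:
            raise ValueError("weights and p-values must align")
        th = tuple(self.thresholds)
        if not th or any(not 0 < x <= 1 for x in th) or any(
            x >= y for x, y in zip(th, th[1:])
        ):
            raise ValueError("thresholds must be strictly increasing in (0, 1]")
        self.thresholds = th


def prs_score(
    genotypes: np.ndarray, prs_model: PrsModel, threshold: float
) -> np.ndarray:
    """Weighted allele-dosage sum over SNPs with discovery p <= threshold,
    standardized to mean 0 / variance 1 across the cohort.

    If no SNP passes (or the raw score is constant) the standardized score is
    all zeros, with a warning.
    """
    geno = np.asarray(genotypes, dtype=float)
    mask = prs_model.snp_pvalues <= threshold
    raw = geno[:, mask] @ prs_model.snp_weights[mask]
    sd = raw.std(ddof=0)
    if not mask.any() or sd == 0:
        warnings.warn(
            f"no informative SNP at P_T={threshold}; returning zero scores",
            stacklevel=2,
        )
        return np.zeros(geno.shape[0])
    return (raw - raw.mean()) / sd


@dataclass(frozen=True)
class PrsAssociationResult:
    beta: float
    se: float
    pvalue: float
    nagelkerke_r2: float
    n: int
    converged: bool
    warning: str | None = None


def _nagelkerke_incremental_r2(ll_full: float, ll_base: float, ll_null: float, n: int) -> float:
    """Nagelkerke R2 of the score over the covariate-only baseline.

    Cox-Snell R2 of full vs baseline, rescaled by the Nagelkerke maximum
    computed from the intercept-only likelihood (PRS-literature convention).
    """
    cox_snell = 1.0 - math.exp(2.0 * (ll_base - ll_full) / n)
    max_r2 = 1.0 - math.exp(2.0 * ll_null / n)
    return cox_snell / max_r2 if max_r2 > 0 else 0.0


def prs_association(
    case_status: np.ndarray,
    score: np.ndarray,
    covariates: np.ndarray | None = None,
) -> PrsAssociationResult:
    """Logistic regression of case status on a polygenic score, adjusting for
    covariates (e.g. genetic ancestry principal components).

    Returns the score coefficient (log odds per unit of score; per SD when
    the score is standardized), its SE and two-sided p, and the incremental
    Nagelkerke R2 versus the covariate-only model.  Degenerate inputs
    (constant score, separation) are flagged rather than raised.
    """
    y = np.asarray(case_status, dtype=float)
    s = np.asarray(score, dtype=float)
    if y.shape[0] != s.shape[0]:
        raise ValueError("case_status and score must align")
    n = y.shape[0]
    if covariates is None:
        covariates = np.empty((n, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    warning = None
    if s.std() == 0:
        return PrsAssociationResult(
            beta=0.0, se=float("inf"), pvalue=1.0, nagelkerke_r2=0.0, n=n,
            converged=False, warning="constant score",
        )
    x_base = sm.add_constant(cov, has_constant="add")
    x_full = np.column_stack([x_base, s])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit_full = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
            fit_base = sm.Logit(y, x_base).fit(disp=0, maxiter=200)
            fit_null = sm.Logit(y, np.ones((n, 1))).fit(disp=0, maxiter=200)
        except Exception as exc:  # separation can abort the MLE outright
            return PrsAssociationResult(
                beta=float("nan"), se=float("inf"), pvalue=1.0, nagelkerke_r2=0.0,
                n=n, converged=False, warning=f"fit failed: {exc}",
            )
    converged = bool(fit_full.mle_retvals.get("converged", True))
    if not converged or not np.isfinite(fit_full.bse[-1]):
        warning = "possible separation: estimates unreliable"
    r2 = _nagelkerke_incremental_r2(fit_full.llf, fit_base.llf, fit_null.llf, n)
    return PrsAssociationResult(
        beta=float(fit_full.params[-1]),
        se=float(fit_full.bse[-1]),
        pvalue=float(fit_full.pvalues[-1]),
        nagelkerke_r2=float(r2),
        n=n,
        converged=converged,
        warning=warning,
    )


def select_best_threshold(
    case_status: np.ndarray,
    genotypes: np.ndarray,
    prs_model: PrsModel,
    covariates: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Score at every P_T and pick the most predictive threshold.

    "Most predictive" is the largest incremental Nagelkerke R2; ties break
    toward the smaller threshold.  Returns the selected P_T and the per
    threshold association table.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pt in prs_model.thresholds:
            score = prs_score(genotypes, prs_model, pt)
            res = prs_association(case_status, score, covariates)
            rows.append(
                {
                    "threshold": pt,
                    "n_snps": int((prs_model.snp_pvalues <= pt).sum()),
                    "beta": res.beta,
                    "se": res.se,
                    "pvalue": res.pvalue,
                    "nagelkerke_r2": res.nagelkerke_r2,
                }
            )
    table = pd.DataFrame(rows)
    best_idx = int(table["nagelkerke_r2"].round(12).idxmax())  # first max -> smaller P_T
    best = float(table.loc[best_idx, "threshold"])
    prs_model.selected_threshold = best
    return best, table


def allelic_sumstats(genotypes: np.ndarray, case_status: np.ndarray) -> pd.DataFrame:
    """Per-SNP marginal log-OR and p-value from allele-count 2x2 tables.

    A lightweight discovery-GWAS stand-in for building :class:`PrsModel`
    weights from simulated data (SNPs are treated as independent).
    """
    geno = np.asarray(genotypes, dtype=float)
    y = np.asarray(case_status, dtype=bool)
    a = geno[y].sum(axis=0)                    # effect alleles in cases
    b = 2.0 * y.sum() - a
    c = geno[~y].sum(axis=0)
    d = 2.0 * (~y).sum() - c
    zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    a, b, c, d = (x + 0.5 * zero for x in (a, b, c, d))
    beta = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    pvals = np.array([p_from_z(z) for z in beta / se])
    return pd.DataFrame(
        {"snp": np.arange(geno.shape[1]), "beta": beta, "se": se, "p": pvals}
    )


# -- hypothesis-testing helpers -------------------------------------------


def z_compare_effects(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float]:
    """Two-sample z-test for equality of two effect sizes.

    z = (beta1 - beta2)/sqrt(se1^2 + se2^2) with a two-sided normal p.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta1 - beta2) / math.sqrt(se1 * se1 + se2 * se2)
    return z, p_from_z(z)


def p_from_z(z: float) -> float:
    """Two-sided normal-tail p-value, 2*(1 - Phi(|z|)), via the stable
    complementary CDF.

    For extreme tails where the p-value drops below the smallest float64
    subnormal, the log survival function is exponentiated in extended
    precision instead, so the result never underflows to exactly zero for
    |z| <= 40.
    """
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    p = 2.0 * stats.norm.sf(abs(z))
    if p > 0.0:
        return float(p)
    return np.exp(np.longdouble(math.log(2.0) + stats.norm.logsf(abs(z))))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


def measure_overlap(
    measure_a: Sequence[bool | float], measure_b: Sequence[bool | float]
) -> tuple[float | None, int]:
    """Percentage of A-positives that are also B-positive.

    Missing values (NaN/None) are excluded pairwise; the count of pairs used
    is returned alongside.  Returns (None, n_used) when no A-positive remains.
    """
    a = pd.array(measure_a)
    b = pd.array(measure_b)
    if len(a) != len(b):
        raise ValueError("measures must be aligned over the same patients")
    keep = ~(pd.isna(a) | pd.isna(b))
    n_used = int(keep.sum())
    a_pos = np.asarray(a[keep], dtype=bool)
    b_pos = np.asarray(b[keep], dtype=bool)
    n_a = int(a_pos.sum())
    if n_a == 0:
        return None, n_used
    return 100.0 * float((a_pos & b_pos).sum()) / n_a, n_used
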