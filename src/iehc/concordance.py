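"""Effect-size concordance between survival and eQTL effects, and enrichment.

Per SNP, a marginal Cox log-hazard effect is estimated with the clinical
covariates adjusted for; per gene, these are regressed (OLS with
intercept) on the eQTL effect sizes of the same SNPs.  Study-wide BH FDR
flags genes whose slopes are significant.  The enrichment step compares
joint-test detection rates (p < 0.05) between genes with significant and
non-significant slopes via a continuity-corrected 2x2 chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from iehc.cox import (
    ConvergenceError,
    DegenerateDesignError,
    SurvivalDataset,
    fit_cox,
)
from iehc.pipeline import GenotypeMatrix, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "EffectPair",
    "ConcordanceResult",
    "TwoByTwoCounts",
    "marginal_cox_effects",
    "gene_regression",
    "concordance_study",
    "enrichment_test",
]

MIN_SHARED_SNPS = 3  # OLS with intercept needs a residual degree of freedom


@dataclass
class EffectPair:
    gene: str
    survival_effects: np.ndarray   # response: marginal Cox log-hazard estimates
    eqtl_effects: np.ndarray       # covariate: eQTL effect sizes

    def __post_init__(self) -> None:
        self.survival_effects = np.asarray(self.survival_effects, dtype=float)
        self.eqtl_effects = np.asarray(self.eqtl_effects, dtype=float)
        if self.survival_effects.shape != self.eqtl_effects.shape:
            raise ValueError("effect vectors differ in length")
        if self.survival_effects.size < MIN_SHARED_SNPS:
            raise ValueError(f"need at least {MIN_SHARED_SNPS} shared SNPs")
        if not (np.isfinite(self.survival_effects).all() and np.isfinite(self.eqtl_effects).all()):
            raise ValueError("effect vectors must be finite")


@dataclass
class ConcordanceResult:
    gene: str
    slope: float
    p_value: float
    r_squared: float
    q_value: float = float("nan")
    undefined_slope: bool = False


@dataclass
class TwoByTwoCounts:
    """(detected, undetected) x (significant slope FDR, non-significant)."""

    a: int  # joint p < 0.05, FDR < threshold
    b: int  # joint p >= 0.05, FDR < threshold
    c: int  # joint p < 0.05, FDR >= threshold
    d: int  # joint p >= 0.05, FDR >= threshold

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")


def marginal_cox_effects(
    G: GenotypeMatrix, pheno: SurvivalDataset, standardize_covariates: bool = True
) -> np.ndarray:
    """Per-SNP marginal Cox log-hazard estimates adjusting for covariates.

    One fit per SNP with design [g_j, X]; monomorphic or non-converged
    SNPs come back as NaN with a log entry.
    """
    X = pheno.covariates
    if X.shape[1] and standardize_covariates:
        sd = X.std(axis=0, ddof=1)
        X = (X[:, sd > 0] - X[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    out = np.full(G.n_snps, np.nan)
    for j in range(G.n_snps):
        g = G.dosages[:, j]
        if np.ptp(g[~np.isnan(g)]) == 0 or np.isnan(g).all():
            logger.info("SNP %s monomorphic; no marginal estimate", G.snp_ids[j])
            continue
        gj = np.where(np.isnan(g), np.nanmean(g), g)
        design = np.column_stack([gj, X]) if X.shape[1] else gj[:, None]
        try:
            fit = fit_cox(pheno, design)
        except (DegenerateDesignError, ConvergenceError) as exc:
            logger.warning("SNP %s: %s", G.snp_ids[j], exc)
            continue
        if fit.converged:
            out[j] = fit.coefficients[0]
        else:
            logger.warning("SNP %s: Cox fit did not converge", G.snp_ids[j])
    return out


def gene_regression(pair: EffectPair) -> ConcordanceResult:
    """OLS of survival effects on eQTL effects (slope t-test, R^2)."""
    x, y = pair.eqtl_effects, pair.survival_effects
    if np.ptp(x) == 0:
        return ConcordanceResult(pair.gene, float("nan"), float("nan"),
                                 float("nan"), undefined_slope=True)
    res = stats.linregress(x, y)
    return ConcordanceResult(
        gene=pair.gene,
        slope=float(res.slope),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
    )


def concordance_study(pairs: list[EffectPair]) -> list[ConcordanceResult]:
    """Per-gene regressions with BH q-values across the testable genes."""
    results = [gene_regression(p) for p in pairs]
    ok = [i for i, r in enumerate(results) if not r.undefined_slope and np.isfinite(r.p_value)]
    if ok:
        q = bh_fdr([results[i].p_value for i in ok])
        for i, qi in zip(ok, q):
            results[i].q_value = float(qi)
    return results


def enrichment_test(counts: TwoByTwoCounts) -> tuple[float, float, float]:
    """Continuity-corrected 1-df chi-square on the 2x2 detection table.

    Returns (statistic, p, rate_ratio) with rate_ratio the detection rate
    among FDR-significant genes over the rate among the rest.  A zero
    margin makes the table untestable (NaN statistic and p).
    """
    t = np.array([[counts.a, counts.b], [counts.c, counts.d]], dtype=float)
    rate1 = counts.a / (counts.a + counts.b) if counts.a + counts.b else np.nan
    rate2 = counts.c / (counts.c + counts.d) if counts.c + counts.d else np.nan
    ratio = rate1 / rate2 if rate2 else np.nan
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        logger.warning("degenerate 2x2 margin; enrichment untestable")
        return float("nan"), float("nan"), float(ratio)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(chi2), float(p), float(ratio)
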