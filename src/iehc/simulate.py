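"""Synthetic data generator for calibration and power experiments.

Emulates the study design the tests were built for: a small expression
cohort (default 165 subjects) in which per-SNP eQTL effects beta are
estimated, and a disjoint survival cohort (default 300 subjects) whose
Weibull event times depend on the SNPs through alpha = beta * theta + b,
b ~ N(0, tau), plus one binary and one continuous covariate (effects 0.5
each).  Genotypes are AR(1)-latent-Gaussian "nearby SNP" blocks: two
independent haplotype-level latent vectors with correlation
ld_rho^{|j-k|} are thresholded at the allele frequency, giving hard-call
dosages with a single LD knob.  Censoring is random: exactly
floor(censor_rate * n) subjects are censored at a uniform fraction of
their true event time.

All operations are pure functions of (config, seed): identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from iehc.combine import DEFAULT_RHO_GRID
from iehc.cox import SurvivalDataset, fit_cox, wald_test
from iehc.kernel import km_score_test
from iehc.pipeline import IEHCConfig, GenotypeMatrix, WeightSet, run_gene

__all__ = [
    "SimConfig",
    "SimReplicate",
    "simulate_genotypes",
    "simulate_eqtl",
    "marginal_eqtl_weights",
    "simulate_survival",
    "simulate_replicate",
    "evaluate_replicate",
    "run_null_calibration",
    "run_power",
]


@dataclass
class SimConfig:
    """Generative protocol parameters (defaults are the study conditions)."""

    n_expr: int = 165              # expression-cohort size
    n_surv: int = 300              # survival-cohort size
    s_range: tuple = (20, 50)      # SNPs per gene, uniform inclusive (mean 35)
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.5            # AR(1) latent correlation between nearby SNPs
    pve: float = 0.3               # expression variance explained by genotypes
    prop_zero: float = 0.3         # fraction of SNPs with zero eQTL effect
    theta: float = 0.0             # eQTL-score (burden) effect on log-hazard
    tau: float = 0.0               # variance of direct SNP effects
    covariate_effects: tuple = (0.5, 0.5)
    weibull_shape: float = 1.0
    weibull_scale: float = 0.01
    censor_rate: float = 0.5
    use_true_beta: bool = False    # weights = true beta instead of marginal estimates
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pve < 1):
            raise ValueError("pve must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")


@dataclass
class SimReplicate:
    G1: np.ndarray
    G2: np.ndarray
    beta: np.ndarray
    beta_hat: np.ndarray
    expression: np.ndarray
    b: np.ndarray
    alpha: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    time: np.ndarray
    status: np.ndarray
    maf: np.ndarray = field(default_factory=lambda: np.empty(0))


def simulate_genotypes(
    n: int, S: int, maf: np.ndarray, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Hard-call dosages with AR(1) latent-Gaussian LD structure.

    Each haplotype allele is 1 when its latent Gaussian exceeds the
    (1 - maf) quantile; the dosage is the sum over the two haplotypes.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf entries must lie in (0, 0.5]")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must lie in [0, 1)")
    thr = stats.norm.isf(maf)

    def latent(size):
        z = rng.standard_normal((size, S))
        if ld_rho > 0:
            out = np.empty_like(z)
            out[:, 0] = z[:, 0]
            c = np.sqrt(1.0 - ld_rho**2)
            for j in range(1, S):
                out[:, j] = ld_rho * out[:, j - 1] + c * z[:, j]
            return out
        return z

    h1 = latent(n) > thr
    h2 = latent(n) > thr
    return (h1.astype(float) + h2.astype(float))


def simulate_eqtl(
    G1: np.ndarray, pve: float, prop_zero: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """eQTL effects with an exact per-replicate PVE target and an expression vector.

    beta_j ~ N(0, 1), an exact floor(prop_zero * S) random subset zeroed,
    then beta rescaled so that empirically Var(G1 beta) = pve/(1-pve) *
    Var(e) with e standard normal; y = G1 beta + e.
    """
    if not (0 < pve < 1):
        raise ValueError("pve must lie in (0, 1)")
    n, S = G1.shape
    for _ in range(100):
        beta = rng.standard_normal(S)
        n_zero = int(np.floor(prop_zero * S))
        if n_zero:
            beta[rng.choice(S, size=n_zero, replace=False)] = 0.0
        e = rng.standard_normal(n)
        g = G1 @ beta
        vg = g.var(ddof=1)
        if vg > 0:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw a nonzero genetic component")
    target = pve / (1.0 - pve) * e.var(ddof=1)
    beta = beta * np.sqrt(target / vg)
    y = G1 @ beta + e
    return beta, y


def marginal_eqtl_weights(G1: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-SNP-at-a-time OLS slopes of expression on dosage (summary-statistic weights)."""
    gc = G1 - G1.mean(axis=0)
    yc = y - y.mean()
    denom = (gc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = gc.T @ yc / denom
    slopes[~np.isfinite(slopes)] = 0.0
    return slopes


def simulate_survival(
    G2: np.ndarray,
    alpha: np.ndarray,
    covariate_effects=(0.5, 0.5),
    shape: float = 1.0,
    scale: float = 0.01,
    censor_rate: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weibull survival times by inverse probability, with random censoring.

    eta = G2 alpha + c1 X1 + c2 X2 (X1 Bernoulli(0.5), X2 standard normal);
    T = (-log U / (scale * exp(eta)))^(1/shape).  Exactly
    floor(censor_rate * n) randomly chosen subjects are censored at a
    uniform fraction of their true time.
    """
    rng = rng or np.random.default_rng()
    n = G2.shape[0]
    X1 = rng.binomial(1, 0.5, size=n).astype(float)
    X2 = rng.standard_normal(n)
    eta = G2 @ alpha + covariate_effects[0] * X1 + covariate_effects[1] * X2
    U = rng.uniform(size=n)
    T = (-np.log(U) / (scale * np.exp(eta))) ** (1.0 / shape)
    status = np.ones(n, dtype=int)
    time = T.copy()
    n_cens = int(np.floor(censor_rate * n))
    if n_cens:
        idx = rng.choice(n, size=n_cens, replace=False)
        status[idx] = 0
        time[idx] = T[idx] * rng.uniform(size=n_cens)
    return time, status, X1, X2


def simulate_replicate(config: SimConfig, rng: np.random.Generator | None = None) -> SimReplicate:
    """One full replicate of the generative protocol."""
    rng = rng or np.random.default_rng(config.seed)
    S = int(rng.integers(config.s_range[0], config.s_range[1] + 1))
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=S)
    G1 = simulate_genotypes(config.n_expr, S, maf, config.ld_rho, rng)
    beta, y = simulate_eqtl(G1, config.pve, config.prop_zero, rng)
    beta_hat = marginal_eqtl_weights(G1, y)
    G2 = simulate_genotypes(config.n_surv, S, maf, config.ld_rho, rng)
    # always consume the draw so the random stream is aligned across
    # (theta, tau) cells under common seeding
    b = np.sqrt(config.tau) * rng.standard_normal(S)
    alpha = beta * config.theta + b
    time, status, X1, X2 = simulate_survival(
        G2, alpha, config.covariate_effects, config.weibull_shape,
        config.weibull_scale, config.censor_rate, rng,
    )
    return SimReplicate(G1=G1, G2=G2, beta=beta, beta_hat=beta_hat, expression=y,
                        b=b, alpha=alpha, X1=X1, X2=X2, time=time, status=status, maf=maf)


def _dataset(rep: SimReplicate) -> SurvivalDataset:
    return SurvivalDataset(
        subject_id=np.arange(rep.time.size),
        time=rep.time,
        status=rep.status,
        covariates=np.column_stack([rep.X1, rep.X2]),
        covariate_names=["X1", "X2"],
    )


def evaluate_replicate(
    rep: SimReplicate,
    config: SimConfig,
    tests: str = "all",
    pipeline_config: IEHCConfig | None = None,
) -> dict:
    """Run the gene-level tests on one replicate.

    ``tests="components"`` computes only (U_theta, U_tau) — enough for the
    statistic-independence check at a fraction of the cost; ``"all"`` runs
    the full six-test battery via the pipeline.
    """
    weights = rep.beta if config.use_true_beta else rep.beta_hat
    data = _dataset(rep)
    if tests == "components":
        s = rep.G2 @ weights
        X = data.covariates
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        design = np.column_stack([s, Xs])
        fit1 = fit_cox(data, design)
        u_theta, p_burden = wald_test(fit1, 0)
        km = km_score_test(data, fit1, design, rep.G2)
        return {"U_theta": u_theta, "U_tau": km.Q, "p_burden": p_burden, "p_tau": km.p_value}
    S = rep.G2.shape[1]
    snps = np.array([f"snp{j}" for j in range(S)], dtype=object)
    alleles_e = np.array(["A"] * S, dtype=object)
    alleles_o = np.array(["G"] * S, dtype=object)
    G = GenotypeMatrix(sample_ids=np.arange(rep.G2.shape[0]), snp_ids=snps,
                       dosages=rep.G2, effect_allele=alleles_e, other_allele=alleles_o)
    W = WeightSet("gene", snps, weights, alleles_e.copy(), alleles_o.copy())
    res = run_gene(G, W, data, pipeline_config or IEHCConfig())
    return {
        "U_theta": res.u_theta, "U_tau": res.u_tau,
        "p_burden": res.p_burden, "p_km": res.p_km, "p_tau": res.p_tau,
        "p_fisher": res.p_fisher, "p_adapt": res.p_adapt,
        "p_optim": res.p_optim, "p_acat": res.p_acat,
    }


def run_null_calibration(
    config: SimConfig | None = None,
    reps: int = 2000,
    seed: int = 0,
    alphas=(0.05, 0.01),
    tests: str = "all",
) -> dict:
    """Type-I-error and statistic-independence report under theta = tau = 0.

    Returns a dict with the per-replicate table, empirical rejection rates
    at each alpha, and the Pearson correlation between U_theta and U_tau
    with a Fisher-z confidence interval.
    """
    config = config or SimConfig()
    if reps < 100:
        raise ValueError("fewer than 100 replicates is not a meaningful calibration")
    if config.theta != 0 or config.tau != 0:
        raise ValueError("null calibration requires theta = 0 and tau = 0")
    rng = np.random.default_rng(seed)
    rows = [evaluate_replicate(simulate_replicate(config, rng), config, tests=tests)
            for _ in range(reps)]
    table = pd.DataFrame(rows)
    u1, u2 = table["U_theta"].to_numpy(), table["U_tau"].to_numpy()
    corr = float(np.corrcoef(u1, u2)[0, 1])
    z = np.arctanh(corr)
    se = 1.0 / np.sqrt(reps - 3)
    ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
    p_corr = float(2 * stats.norm.sf(abs(z) / se))
    rates = {}
    for col in [c for c in table.columns if c.startswith("p_")]:
        rates[col] = {a: float((table[col] <= a).mean()) for a in alphas}
    return {
        "table": table,
        "rejection_rates": rates,
        "corr_U": corr,
        "corr_ci": ci,
        "corr_p": p_corr,
        "reps": reps,
    }


def run_power(
    theta_values=(0.0, 0.1, 0.2, 0.3, 0.4),
    tau_values=(0.0, 0.02, 0.04),
    reps: int = 500,
    config: SimConfig | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection proportions per (theta, tau) cell and per test at level alpha.

    Cells with theta = tau = 0 are skipped (that is the null, not power).
    Shared seeding across cells keeps power monotone in effect size up to
    Monte-Carlo noise.
    """
    base = config or SimConfig()
    out = []
    for theta in theta_values:
        for tau in tau_values:
            if theta == 0 and tau == 0:
                continue
            cfg = replace(base, theta=theta, tau=tau)
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                [evaluate_replicate(simulate_replicate(cfg, rng), cfg, tests="all")
                 for _ in range(reps)]
            )
            for col in [c for c in table.columns if c.startswith("p_")]:
                pw = float((table[col] <= alpha).mean())
                out.append({
                    "theta": theta, "tau": tau, "test": col[2:],
                    "power": pw, "mc_se": float(np.sqrt(pw * (1 - pw) / reps)),
                    "reps": reps,
                })
    return pd.DataFrame(out)
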