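"""Variance-component (kernel-machine) score test for the Cox model.

Tests H0: tau = 0 where per-SNP effects b_j ~ N(0, tau), using the linear
kernel K = G G^T.  The score statistic is Q = r^T K r with r the null-model
martingale residuals; under the null Q is distributed as a mixture
sum_l lambda_l chi^2_1 whose weights are the nonzero eigenvalues of
V~^{1/2} K V~^{1/2}, with V~ the information operator in the linear
predictor projected orthogonally to the null design.  Tail probabilities
come from characteristic-function inversion (Davies/Imhof), with a
moment-matching (Liu) and a Monte-Carlo fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from iehc.cox import CoxFit, SurvivalDataset, information_operator

__all__ = [
    "KernelScoreResult",
    "km_score_test",
    "davies_pvalue",
    "mixture_quantile",
    "AlignmentError",
]

EIG_REL_TOL = 1e-10  # drop eigenvalues below this times the largest
_P_TINY = 1e-300


class AlignmentError(ValueError):
    """Genotype rows do not match the fitted cohort."""


@dataclass
class KernelScoreResult:
    Q: float
    eigenvalues: np.ndarray
    p_value: float
    tail_method: str


def _liu_params(lam: np.ndarray):
    """Liu-Tang-Zhang moment-matched noncentral chi-square parameters."""
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_x = dof + delta
    sigma_x = np.sqrt(2 * (dof + 2 * delta))
    return dof, delta, mu_x, sigma_x, c1, np.sqrt(2 * c2)

def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    dof, delta, mu_x, sigma_x, mu_q, sigma_q = _liu_params(lam)
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, dof, delta))


def _liu_quantile(p_upper: float, lam: np.ndarray) -> float:
    p_upper = max(p_upper, 1e-280)
    dof, delta, mu_x, sigma_x, mu_q, sigma_q = _liu_params(lam)
    x = stats.ncx2.isf(p_upper, dof, delta)
    q = float((x - mu_x) / sigma_x * sigma_q + mu_q)
    if not np.isfinite(q):
        # conservative envelope: mixture <= lam_max * chi^2_L
        q = float(lam.max() * stats.chi2.isf(p_upper, df=lam.size))
    return q


def _imhof(q: float, lam: np.ndarray) -> tuple[float, float]:
    """Imhof characteristic-function inversion; returns (p, abs error est).

    The integrand sin(theta(u)) / (u rho(u)) with
    theta = 0.5 sum arctan(lam u) - q u / 2 decays like u^{-1-L/2}, which is
    slow for few mixture components.  The integral is therefore split at U:
    an adaptive rule on (0, U] plus two Fourier-weighted (QAWF) tails using
    sin(theta) = sin(a) cos(qu/2) - cos(a) sin(qu/2), whose non-oscillatory
    factors involve only the slowly varying a(u) = 0.5 sum arctan(lam u).
    """

    def a(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def g(u):
        return np.exp(-0.25 * np.sum(np.log1p((lam * u) ** 2))) / u

    def integrand(u):
        return np.sin(a(u) - 0.5 * q * u) * g(u)

    # U where the arctan parts are nearly flat (their derivative ~ sum 1/(lam u^2))
    U = max(float(np.sum(1.0 / lam)) * 20.0, 2.0 / max(q, 1e-3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        body, e_body = integrate.quad(
            integrand, 0.0, U, limit=800, epsabs=1e-11, epsrel=1e-9)
        t_cos, e_cos = integrate.quad(
            lambda u: np.sin(a(u)) * g(u), U, np.inf,
            weight="cos", wvar=0.5 * q, limit=400, epsabs=1e-11)
        t_sin, e_sin = integrate.quad(
            lambda u: np.cos(a(u)) * g(u), U, np.inf,
            weight="sin", wvar=0.5 * q, limit=400, epsabs=1e-11)
    val = body + t_cos - t_sin
    return 0.5 + val / np.pi, e_body + e_cos + e_sin


def davies_pvalue(
    q: float, eigenvalues: np.ndarray, mc_draws: int = 10**6
) -> tuple[float, str]:
    """Upper-tail probability of sum_l lambda_l chi^2_1 at ``q``.

    Exact-inversion (Davies/Imhof) integration; falls back to the Liu
    moment-matching approximation when the integrator misbehaves, and to a
    seeded Monte-Carlo estimate as a last resort.  Returns (p, tail_method).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("at least one positive eigenvalue is required")
    if q < 0:
        raise ValueError("quadratic-form statistic must be nonnegative")
    if q == 0:
        return 1.0, "davies"
    if not np.isfinite(q):
        return _P_TINY, "davies"
    if lam.size == 1:
        # rank-one kernel: exact scaled 1-df chi-square tail
        return float(stats.chi2.sf(q / lam[0], df=1)), "davies"
    if np.allclose(lam, lam[0], rtol=1e-12):
        return float(stats.chi2.sf(q / lam[0], df=lam.size)), "davies"
    try:
        # grid-based inversion first (fast, absolute accuracy ~1e-7); the
        # adaptive Fourier-weighted rule covers small mixtures and far tails
        p = float(_imhof_many(np.array([q]), lam)[0])
        if p >= 1e-5 and p <= 1.0:
            return p, "davies"
    except _TooHard:
        pass
    try:
        p, err = _imhof(q, lam)
        if 0.0 < p <= 1.0 and err < 1e-5:
            return float(min(p, 1.0)), "davies"
    except Exception:  # pragma: no cover - integrator blow-up
        pass
    p = _liu_pvalue(q, lam)
    if 0.0 < p <= 1.0:
        return p, "liu_moment"
    rng = np.random.default_rng(161803398)  # fixed: a reproducible last resort
    draws = rng.chisquare(1, size=(mc_draws, lam.size)) @ lam
    return float(max((draws >= q).mean(), 1.0 / mc_draws)), "monte_carlo"


class _TooHard(Exception):
    """Batch integration grid would be too large; use the scalar path."""


def _imhof_many(xs: np.ndarray, lam: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Vectorised Imhof tail probabilities for many statistics, one mixture.

    Midpoint rule on (0, U] where U comes from the analytic envelope bound
    |integrand| <= u^{-1-L/2} prod(lam)^{-1/2}; the grid is refined until
    two successive doublings agree.  Raises ``_TooHard`` for mixtures with
    few components (slow envelope decay), which the caller integrates with
    the adaptive scalar rule instead.
    """
    lam = lam[lam > 0]
    L = lam.size
    if L < 8:
        raise _TooHard
    loglam_sum = float(np.log(lam).sum())
    logU = (-np.log(tol * np.pi * L / 2.0) - 0.5 * loglam_sum) / (0.5 * L)
    U = float(np.exp(min(logU, 30.0)))
    xmax = float(max(xs.max(), lam.sum()))
    # keep the phase increment per step below ~0.5 rad
    n_est = U * 0.5 * (lam.sum() + xmax) / 0.5 + 64
    if not np.isfinite(n_est) or n_est > (1 << 18):
        raise _TooHard
    n = int(np.ceil(n_est))
    prev = None
    for _ in range(4):
        u = (np.arange(n) + 0.5) * (U / n)
        lu = np.outer(u, lam)
        a = 0.5 * np.arctan(lu).sum(axis=1)
        base = np.exp(-0.25 * np.log1p(lu**2).sum(axis=1)) / u
        integ = np.sin(a[None, :] - 0.5 * np.outer(xs, u)) @ base * (U / n)
        p = 0.5 + integ / np.pi
        if prev is not None and np.max(np.abs(p - prev)) < 1e-7:
            return np.clip(p, 0.0, 1.0)
        prev = p
        n *= 2
        if n > (1 << 19):
            break
    return np.clip(prev, 0.0, 1.0)


def _mixture_sf_many(xs: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Batch upper-tail probabilities; falls back to per-value davies."""
    xs = np.asarray(xs, dtype=float)
    try:
        return _imhof_many(xs, np.asarray(lam, dtype=float))
    except _TooHard:
        return np.array([davies_pvalue(float(x), lam)[0] for x in xs])


def _mixture_quantile_fast(p_upper: float, lam: np.ndarray) -> float:
    """Bisection quantile using the batch evaluator (scalar-quad fallback)."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 1:
        return float(lam[0] * stats.chi2.isf(p_upper, df=1))
    if p_upper < 1e-8:
        # below the integrators' absolute resolution; the moment-matched
        # quantile is accurate enough for downstream use at these levels
        return float(_liu_quantile(p_upper, lam))
    if lam.size < 8:
        return mixture_quantile(p_upper, lam)
    lo = hi = max(_liu_quantile(p_upper, lam), 1e-12)
    f = lambda x: float(_mixture_sf_many(np.array([x]), lam)[0]) - p_upper
    flo = f(lo)
    for _ in range(200):
        if flo >= 0:
            break
        lo *= 0.5
        flo = f(lo)
    fhi = f(hi)
    for _ in range(200):
        if fhi <= 0:
            break
        hi *= 2.0
        fhi = f(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-7 * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def mixture_quantile(p_upper: float, eigenvalues: np.ndarray) -> float:
    """Upper p-quantile of the chi-square mixture (inverse of davies_pvalue)."""
    from scipy.optimize import brentq

    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 1:
        return float(lam[0] * stats.chi2.isf(p_upper, df=1))
    if p_upper < 1e-12:
        return float(_liu_quantile(p_upper, lam))
    x0 = max(_liu_quantile(p_upper, lam), 1e-12)
    f = lambda x: davies_pvalue(x, lam)[0] - p_upper
    # f is decreasing in x: shrink lo until f(lo) >= 0, grow hi until f(hi) <= 0
    lo = hi = x0
    flo = f(lo)
    for _ in range(200):
        if flo >= 0:
            break
        lo *= 0.5
        flo = f(lo)
    fhi = f(hi)
    for _ in range(200):
        if fhi <= 0:
            break
        hi *= 2.0
        fhi = f(hi)
    if flo == 0:
        return float(lo)
    if fhi == 0:
        return float(hi)
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-10))


def km_score_test(
    data: SurvivalDataset,
    null_fit: CoxFit,
    null_design: np.ndarray | None,
    G: np.ndarray,
) -> KernelScoreResult:
    """Kernel-machine score test of tau = 0 with the linear kernel G G^T.

    ``null_fit`` must be the Cox fit on ``null_design`` (covariates only for
    the plain test; covariates plus the fitted burden column for the
    decorrelated variant).  Eigenvalues are computed on the S x S
    cross-product G^T V~ G, which shares the nonzero spectrum of
    V~^{1/2} G G^T V~^{1/2}.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != data.n:
        raise AlignmentError("genotype rows do not match the fitted cohort")
    r = null_fit.martingale_residuals
    score = G.T @ r
    Q = float(score @ score)
    if not np.any(G):
        return KernelScoreResult(Q=0.0, eigenvalues=np.empty(0), p_value=1.0, tail_method="davies")

    V = information_operator(data.time, data.status, null_fit.linear_predictor, null_fit.ties)
    X = None if null_design is None else np.atleast_2d(np.asarray(null_design, dtype=float))
    if X is not None and X.shape[1] > 0:
        VX = V @ X
        M = X.T @ VX
        VG = V @ G - VX @ np.linalg.solve(M, VX.T @ G)
    else:
        VG = V @ G
    A = G.T @ VG
    A = 0.5 * (A + A.T)
    lam = np.linalg.eigvalsh(A)[::-1]
    lam = lam[lam > EIG_REL_TOL * max(lam[0], 0.0)] if lam.size and lam[0] > 0 else np.empty(0)
    if lam.size == 0:
        return KernelScoreResult(Q=Q, eigenvalues=lam, p_value=1.0, tail_method="davies")
    p, method = davies_pvalue(Q, lam)
    return KernelScoreResult(Q=Q, eigenvalues=lam, p_value=float(p), tail_method=method)
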