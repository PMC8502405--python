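"""Combining the decorrelated burden and variance-component statistics.

The two-stage construction makes the burden Wald statistic U_theta and the
kernel-machine score U_tau asymptotically independent, so their p-values
can be combined directly:

* Fisher:  T = -2(log p_theta + log p_tau) against a 4-df chi-square.
* adapt:   binary-subset adaptively weighted Fisher — the best of
  {Z_theta, Z_tau, Z_theta + Z_tau}, calibrated exactly under independent
  uniform nulls.
* optim:   SKAT-O-style optimal linear combination T_rho =
  rho U_theta + (1 - rho) U_tau over a rho grid, calibrated by exact
  one-dimensional conditioning on U_theta.
* ACAT:    Cauchy combination of arbitrary (possibly dependent) p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from iehc.kernel import (
    KernelScoreResult,
    _mixture_quantile_fast,
    _mixture_sf_many,
    davies_pvalue,
)

__all__ = [
    "CombinationResult",
    "fisher_combine",
    "adapt_combine",
    "optim_combine",
    "acat_combine",
    "DEFAULT_RHO_GRID",
]

# denser near zero: small rho keeps most weight on the variance component
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.25, 0.5, 1.0)

_P_FLOOR = 1e-300


@dataclass
class CombinationResult:
    p_fisher: float
    p_adapt: float
    p_optim: float
    rho_selected: float
    rho_grid: np.ndarray
    Z_theta: float
    Z_tau: float
    T_rho: np.ndarray


def _clamp_p(p: float, name: str = "p") -> float:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} outside [0, 1]: {p}")
    if p == 0.0:
        import logging

        logging.getLogger(__name__).warning("%s = 0 clamped to %g", name, _P_FLOOR)
        return _P_FLOOR
    return p


def fisher_combine(p_theta: float, p_tau: float) -> float:
    """Fisher's combination of two independent p-values (4-df chi-square tail)."""
    p1 = _clamp_p(p_theta, "p_theta")
    p2 = _clamp_p(p_tau, "p_tau")
    T = -2.0 * (math.log(p1) + math.log(p2))
    return float(stats.chi2.sf(T, df=4))


def adapt_combine(p_theta: float, p_tau: float) -> float:
    """Adaptively weighted Fisher combination with binary subset weights.

    Candidate statistics are Z_theta (2-df), Z_tau (2-df) and their sum
    (4-df); the observed statistic is the smallest of the three candidate
    p-values, i.e. min(p_theta, p_tau, p_fisher).  The returned p-value is
    the exact null probability, for independent uniforms, that this minimum
    falls at or below the observed value.
    """
    p1 = _clamp_p(p_theta, "p_theta")
    p2 = _clamp_p(p_tau, "p_tau")
    pf = fisher_combine(p1, p2)
    m = min(p1, p2, pf)
    if m >= 1.0:
        return 1.0
    # complement event: p1 > m, p2 > m and p1*p2 > C with
    # C = exp(-q4/2), q4 the m-level upper quantile of the 4-df chi-square
    C = math.exp(-0.5 * stats.chi2.isf(m, df=4))

    def survive_len(x):  # measure of admissible p2 given p1 = x
        lo = max(m, C / x)
        return max(0.0, 1.0 - lo)

    pts = sorted({v for v in (C, C / m if m > 0 else 1.0) if m < v < 1.0})
    comp, _ = integrate.quad(survive_len, m, 1.0, points=pts or None, limit=200)
    p = 1.0 - comp
    return float(min(max(p, m), 1.0))


def optim_combine(
    U_theta: float,
    km: KernelScoreResult,
    rho_grid=DEFAULT_RHO_GRID,
    n_nodes: int = 64,
) -> tuple[float, float]:
    """Optimal linear combination T_rho = rho U_theta + (1-rho) U_tau.

    For each rho the null of T_rho is the chi-square mixture with weights
    {rho} union {(1-rho) lambda_l}; the observed statistic is the minimum
    p over the grid and the final p-value is computed exactly under
    independence of (U_theta, U_tau) by conditioning on U_theta ~ chi^2_1:

        p = 1 - int_0^{q_1} F_tau( min_{rho<1} (q_rho - rho u)/(1-rho) ) f(u) du

    where q_rho is the min-p-level upper quantile of T_rho's null mixture.
    Returns (p, rho_selected); ties on the argmin go to the smallest rho.
    """
    grid = np.unique(np.asarray(rho_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty rho grid")
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("rho grid must lie in [0, 1]")
    lam = np.asarray(km.eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("kernel result carries no positive eigenvalues")
    U_tau = float(km.Q)

    eigsets, T_rho, p_rho = [], [], []
    for rho in grid:
        T = rho * U_theta + (1.0 - rho) * U_tau
        eigs = np.concatenate(([rho] if rho > 0 else [], (1.0 - rho) * lam if rho < 1 else []))
        eigsets.append(eigs)
        T_rho.append(T)
        p = float(_mixture_sf_many(np.array([T]), eigs)[0])
        if p < 1e-5:
            # below the grid evaluator's resolution: use the full cascade
            p = davies_pvalue(T, eigs)[0]
        p_rho.append(max(p, _P_FLOOR))
    T_rho = np.asarray(T_rho)
    p_rho = np.asarray(p_rho)
    k = int(np.argmin(p_rho))  # first occurrence = smallest rho on ties
    minp = float(p_rho[k])
    rho_sel = float(grid[k])
    if grid.size == 1:
        return minp, rho_sel

    q_rho = np.array([_mixture_quantile_fast(minp, eigs) for eigs in eigsets])
    if not np.all(np.isfinite(q_rho)):
        # quantiles beyond numerical reach; the Bonferroni bound over the
        # grid is the honest fallback at these extreme levels
        return float(min(minp * grid.size, 1.0)), rho_sel
    has_one = grid[-1] == 1.0
    u_max = q_rho[-1] if has_one else float(stats.chi2.isf(1e-16, df=1))
    sub = grid < 1.0
    rhos = grid[sub]
    qs = q_rho[sub]

    # substitute u = w^2: chi^2_1 density times du becomes the half-normal
    # sqrt(2/pi) exp(-w^2/2) dw, removing the u^{-1/2} singularity
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    w_hi = math.sqrt(u_max)
    w = 0.5 * w_hi * (nodes + 1.0)
    wq = 0.5 * w_hi * weights
    u = w**2
    xs = np.min((qs[None, :] - np.outer(u, rhos)) / (1.0 - rhos[None, :]), axis=1)
    F = np.zeros_like(xs)
    F[~np.isfinite(xs)] = 1.0  # unbounded region: the mixture CDF is 1
    pos = np.isfinite(xs) & (xs > 0)
    if pos.any():
        F[pos] = 1.0 - _mixture_sf_many(xs[pos], lam)
    integral = float(np.sum(wq * F * np.sqrt(2.0 / math.pi) * np.exp(-0.5 * w**2)))
    p = 1.0 - integral
    return float(min(max(p, minp * (1.0 - 1e-12)), 1.0)), rho_sel


def combine_all(
    p_theta: float,
    p_tau: float,
    U_theta: float,
    km: KernelScoreResult,
    rho_grid=DEFAULT_RHO_GRID,
) -> CombinationResult:
    """All three joint combinations of one gene's component results."""
    grid = np.unique(np.asarray(rho_grid, dtype=float))
    T_rho = np.array([r * U_theta + (1 - r) * km.Q for r in grid])
    p_optim, rho_sel = optim_combine(U_theta, km, rho_grid)
    return CombinationResult(
        p_fisher=fisher_combine(p_theta, p_tau),
        p_adapt=adapt_combine(p_theta, p_tau),
        p_optim=p_optim,
        rho_selected=rho_sel,
        rho_grid=grid,
        Z_theta=-2.0 * math.log(max(p_theta, _P_FLOOR)),
        Z_tau=-2.0 * math.log(max(p_tau, _P_FLOOR)),
        T_rho=T_rho,
    )


def acat_combine(p_values, weights=None) -> float:
    """Aggregated Cauchy association test (ACAT) omnibus p-value.

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i;  p = 0.5 - arctan(T)/pi.
    Very small p_i use the tangent's asymptote w_i / (p_i pi); p_i at 1 are
    clamped just below it.  Valid for dependent inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative with a positive sum")
    p = np.minimum(p, 1.0 - 1e-16)
    small = p < 1e-16
    terms = np.empty_like(p)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    terms[small] = 1.0 / (p[small] * np.pi)
    T = float(np.sum(w * terms) / w.sum())
    return float(min(max(0.5 - math.atan(T) / math.pi, _P_FLOOR), 1.0))
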