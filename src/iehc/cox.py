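"""Cox proportional-hazards engine by maximum partial likelihood.

Everything the gene-level tests are built on lives here: Newton–Raphson
fitting with step-halving (Efron or Breslow tie handling), Wald tests,
the Breslow baseline cumulative hazard, score-based martingale residuals
r_i = d_i - Lambda0(t_i) * exp(eta_i), and the n x n observed-information
operator of the log partial likelihood with respect to the linear
predictor (the ``V`` matrix of the kernel-machine score test).

The martingale residuals are computed as the exact gradient of the log
partial likelihood in eta (with the tie correction of the chosen method),
so they sum to zero identically and ``G.T @ r`` is the exact score
statistic for a genotype block added to the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "CoxFit",
    "fit_cox",
    "wald_test",
    "information_operator",
    "DegenerateDesignError",
    "NoEventsError",
    "DegenerateVarianceError",
    "ConvergenceError",
]


class DegenerateDesignError(ValueError):
    """Design matrix carries no partial-likelihood information (constant or collinear column)."""


class NoEventsError(ValueError):
    """All observations censored; the partial likelihood is flat."""


class DegenerateVarianceError(ValueError):
    """Non-positive variance estimate where a positive one is required."""


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration budget."""


@dataclass
class SurvivalDataset:
    """One cohort: observed times t_i > 0, event indicators d_i, covariates X.

    ``covariates`` may have zero columns (null model).
    """

    subject_id: np.ndarray
    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        n = self.time.shape[0]
        if self.covariates.shape[0] != n:
            if self.covariates.shape == (1, 0):  # empty design shorthand
                self.covariates = np.empty((n, 0))
            else:
                raise ValueError("covariate matrix row count does not match times")
        if n < 2:
            raise ValueError("need at least two subjects")
        if np.any(self.time <= 0) or np.any(~np.isfinite(self.time)):
            raise ValueError("all survival times must be positive and finite")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be binary 0/1")
        self.status = self.status.astype(int)
        if self.status.sum() < 1:
            raise NoEventsError("at least one event is required")
        if np.any(~np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing/non-finite entries")
        if not self.covariate_names:
            self.covariate_names = [f"x{k}" for k in range(self.covariates.shape[1])]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


@dataclass
class CoxFit:
    """A fitted Cox model and the derived quantities the tests consume."""

    coefficients: np.ndarray
    coefficient_covariance: np.ndarray
    log_partial_likelihood: float
    linear_predictor: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    martingale_residuals: np.ndarray
    converged: bool
    n_iterations: int
    ties: str = "efron"

    def cumhaz_at(self, t: np.ndarray) -> np.ndarray:
        """Right-continuous step interpolation of the baseline cumulative hazard."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, dtype=float), side="right")
        out = np.concatenate(([0.0], self.baseline_cumhaz))
        return out[idx]


def _prepare(time: np.ndarray, status: np.ndarray):
    """Sort ascending by time and group tied times.

    Returns (order, group start indices, per-group event index lists).
    """
    order = np.argsort(time, kind="stable")
    ts = time[order]
    # group boundaries of distinct times
    starts = np.flatnonzero(np.concatenate(([True], ts[1:] != ts[:-1])))
    return order, ts, starts


def _pl_quantities(ts, ds, Zs, beta, ties, *, need_hessian=True):
    """Log partial likelihood, gradient and information in beta on sorted data."""
    n, q = Zs.shape
    eta = Zs @ beta if q else np.zeros(n)
    # the partial likelihood is invariant to adding a constant to eta, so a
    # max-shift is a safe guard against overflowing exponentials
    eta = eta - eta.max()
    e = np.exp(eta)
    rc_e = np.cumsum(e[::-1])[::-1]
    if q:
        ze = Zs * e[:, None]
        rc_ze = np.cumsum(ze[::-1], axis=0)[::-1]
        if need_hessian:
            zze = ze[:, :, None] * Zs[:, None, :]
            rc_zze = np.cumsum(zze[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(q)
    info = np.zeros((q, q))
    starts = np.flatnonzero(np.concatenate(([True], ts[1:] != ts[:-1])))
    ends = np.append(starts[1:], n)
    gsize = np.diff(np.append(starts, n))
    gstart = np.repeat(starts, gsize)
    ev_per_group = np.add.reduceat(ds, starts)
    if ev_per_group.max() == 1:
        # no tied event times: fully vectorised (Efron == Breslow here)
        ev = np.flatnonzero(ds == 1)
        S = rc_e[gstart[ev]]
        ll = float((eta[ev] - np.log(S)).sum())
        if q:
            zbar = rc_ze[gstart[ev]] / S[:, None]
            grad = Zs[ev].sum(axis=0) - zbar.sum(axis=0)
            if need_hessian:
                info = (rc_zze[gstart[ev]] / S[:, None, None]).sum(axis=0) \
                    - np.einsum("ij,ik->jk", zbar, zbar)
        return ll, grad, info
    for i0, i1 in zip(starts, ends):
        ev = i0 + np.flatnonzero(ds[i0:i1] == 1)
        d = ev.size
        if d == 0:
            continue
        ll += eta[ev].sum() if q else 0.0
        if q:
            grad += Zs[ev].sum(axis=0)
        S_R = rc_e[i0]
        eD = e[ev].sum()
        if q:
            Z_R = rc_ze[i0]
            ZD = (Zs[ev] * e[ev, None]).sum(axis=0)
            if need_hessian:
                ZZ_R = rc_zze[i0]
                ZZD = np.einsum("ij,ik,i->jk", Zs[ev], Zs[ev], e[ev])
        fracs = np.arange(d) / d if (ties == "efron" and d > 1) else np.zeros(d)
        for frac in fracs:
            den = S_R - frac * eD
            ll -= np.log(den)
            if q:
                zbar = (Z_R - frac * ZD) / den
                grad -= zbar
                if need_hessian:
                    info += (ZZ_R - frac * ZZD) / den - np.outer(zbar, zbar)
    return ll, grad, info


def fit_cox(
    data: SurvivalDataset,
    design: np.ndarray | None = None,
    ties: str = "efron",
    max_iter: int = 50,
    tol_loglik: float = 1e-9,
    tol_grad: float = 1e-6,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step-halving.

    Parameters
    ----------
    data
        Times and event indicators (the dataset's own covariate block is
        ignored here; pass the full design explicitly).
    design
        n x q design matrix; ``None`` or zero columns fits the null model.
    ties
        ``"efron"`` (default) or ``"breslow"``.

    Raises
    ------
    DegenerateDesignError
        For a constant or exactly collinear design column.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    n = data.n
    Z = np.empty((n, 0)) if design is None else np.atleast_2d(np.asarray(design, dtype=float))
    if Z.shape[0] != n:
        raise ValueError("design row count does not match dataset")
    q = Z.shape[1]
    if q and np.any(np.ptp(Z, axis=0) == 0):
        raise DegenerateDesignError("design contains a constant column")
    order, ts, _ = _prepare(data.time, data.status)
    ds = data.status[order]
    Zs = Z[order]

    beta = np.zeros(q)
    ll, grad, info = _pl_quantities(ts, ds, Zs, beta, ties)
    converged = q == 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if q == 0:
            break
        if np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise DegenerateDesignError("singular information matrix (collinear design)") from None
        new_beta, new_ll = beta, ll
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_ll, _, _ = _pl_quantities(ts, ds, Zs, cand, ties, need_hessian=False)
            if cand_ll >= ll - 1e-14:
                new_beta, new_ll = cand, cand_ll
                break
            scale *= 0.5
        else:
            break  # no improving step
        improved = new_ll - ll
        beta = new_beta
        ll, grad, info = _pl_quantities(ts, ds, Zs, beta, ties)
        if abs(improved) < tol_loglik * (abs(ll) + 1.0) and np.max(np.abs(grad)) < 1e-3:
            converged = True
            break
    if q and np.max(np.abs(grad)) < 1e-4:
        # step-halving can stall within rounding error of the optimum;
        # a near-zero gradient is the operative convergence statement
        converged = True
    if not converged:
        logger.warning("Cox fit did not converge after %d iterations (|grad|=%g)",
                       n_iter, np.max(np.abs(grad)) if q else 0.0)

    if q:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise DegenerateDesignError("singular information at the optimum") from None
    else:
        cov = np.empty((0, 0))

    eta = Z @ beta if q else np.zeros(n)
    resid, bl_times, bl_ch = _residuals_and_baseline(data.time, data.status, eta, ties)
    return CoxFit(
        coefficients=beta,
        coefficient_covariance=cov,
        log_partial_likelihood=float(ll),
        linear_predictor=eta,
        baseline_times=bl_times,
        baseline_cumhaz=bl_ch,
        martingale_residuals=resid,
        converged=bool(converged),
        n_iterations=n_iter,
        ties=ties,
    )


def _residuals_and_baseline(time, status, eta, ties):
    """Score-based martingale residuals and the Breslow-type baseline cumhaz.

    r_i = d_i - exp(eta_i) * H_i where H_i accumulates 1/den over event
    groups with t <= t_i, with Efron's own-group downweighting (1 - l/d) for
    the tied events themselves.  Sum of r is exactly zero.
    """
    n = time.shape[0]
    order, ts, starts = _prepare(time, status)
    ds = status[order]
    shift = eta.max()
    etas = eta[order] - shift
    e = np.exp(etas)
    rc_e = np.cumsum(e[::-1])[::-1]
    ends = np.append(starts[1:], n)
    inc = []          # per event-group baseline increment (sum_l 1/den_l)
    gtimes = []
    own_adj = np.zeros(n)  # per-subject own-group subtraction sum_l (l/d)/den_l
    for i0, i1 in zip(starts, ends):
        ev = i0 + np.flatnonzero(ds[i0:i1] == 1)
        d = ev.size
        if d == 0:
            continue
        S_R = rc_e[i0]
        eD = e[ev].sum()
        fracs = np.arange(d) / d if (ties == "efron" and d > 1) else np.zeros(d)
        dens = S_R - fracs * eD
        inc.append(np.sum(1.0 / dens))
        gtimes.append(ts[i0])
        own_adj[ev] = np.sum(fracs / dens)
    gtimes = np.asarray(gtimes)
    cum = np.cumsum(inc)
    # hazard accumulated by each subject while at risk
    H = np.concatenate(([0.0], cum))[np.searchsorted(gtimes, ts, side="right")] - own_adj
    resid_sorted = ds - e * H
    resid = np.empty(n)
    resid[order] = resid_sorted
    # e * H is invariant to the eta shift; the reported baseline is not, so
    # rescale it back to the original linear-predictor scale.
    return resid, gtimes, cum * np.exp(-shift)


def information_operator(
    time: np.ndarray, status: np.ndarray, eta: np.ndarray, ties: str = "efron"
) -> np.ndarray:
    """n x n negative Hessian of the log partial likelihood in the linear predictor.

    For event group k with Efron pass l, with weights
    u = c * exp(eta) / den  (c = 1 on the risk set, 1 - l/d on the tied
    events), the contribution is diag(u) - u u^T.  Without tied events this
    collapses to the vectorised Breslow form
    ``diag(e*H) - outer(e, e) * min(A_i, A_j)`` with
    ``A(t) = sum_{event times <= t} 1/S^2``.
    """
    n = time.shape[0]
    order, ts, starts = _prepare(time, status)
    ds = status[order]
    etas = eta[order] - eta.max()
    e = np.exp(etas)
    rc_e = np.cumsum(e[::-1])[::-1]
    ends = np.append(starts[1:], n)
    group_d = np.array([ds[i0:i1].sum() for i0, i1 in zip(starts, ends)])
    has_ties = np.any(group_d > 1)

    if not has_ties or ties == "breslow":
        ev_groups = group_d > 0
        S = rc_e[starts[ev_groups]]
        d = group_d[ev_groups]
        gtimes = ts[starts[ev_groups]]
        idx = np.searchsorted(gtimes, ts, side="right")
        Hcum = np.concatenate(([0.0], np.cumsum(d / S)))
        Acum = np.concatenate(([0.0], np.cumsum(d / S**2)))
        Hs, As = Hcum[idx], Acum[idx]
        V = -np.outer(e, e) * np.minimum.outer(As, As)
        V[np.diag_indices(n)] += e * Hs
    else:
        V = np.zeros((n, n))
        for i0, i1 in zip(starts, ends):
            ev = i0 + np.flatnonzero(ds[i0:i1] == 1)
            dk = ev.size
            if dk == 0:
                continue
            eD = e[ev].sum()
            S_R = rc_e[i0]
            c = np.zeros(n)
            c[i0:] = 1.0
            for l in range(dk):
                frac = l / dk
                cl = c.copy()
                cl[ev] = 1.0 - frac
                u = cl * e / (S_R - frac * eD)
                V -= np.outer(u, u)
                V[np.diag_indices(n)] += u
    # back to original subject order
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return V[np.ix_(inv, inv)]


def wald_test(fit: CoxFit, index: int = 0) -> tuple[float, float]:
    """1-df Wald chi-square test of a single coefficient.

    Returns (statistic, p); statistic = (coef / se)^2, p from the upper tail
    of a chi-square with one degree of freedom.
    """
    var = fit.coefficient_covariance[index, index]
    if not np.isfinite(var) or var <= 0:
        raise DegenerateVarianceError("non-positive variance estimate")
    stat = float(fit.coefficients[index] ** 2 / var)
    return stat, float(stats.chi2.sf(stat, df=1))
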