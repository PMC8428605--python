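"""Constrained maximum-likelihood estimation of the two mixing distributions.

The estimator maximizes the mixture log-likelihood over the product of two
probability simplices, subject to unimodality of the effect distribution
``g`` expressed as ordering constraints around the mode:
``g_k <= g_{k+1}`` left of the mode and ``g_k >= g_{k+1}`` right of it.
The variance distribution ``h`` is unconstrained apart from the simplex.

The solver is sequential quadratic programming (SLSQP) with analytic
gradients, wrapped in an outer loop that declares convergence when the
relative objective change drops below ``tol``; any residual constraint
violation is removed by a final projection (clip / order-fix / renormalize)
that perturbs the solution by no more than the violation itself.  A
brute-force mesh enumerator over tiny grids (`oracle_fit_mesh`) serves as an
independent check of the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .model_core import (
    ComponentLogLik,
    EffectGrid,
    SummaryStats,
    VarianceGrid,
    build_effect_grid,
    build_variance_grid,
    component_loglik,
    mixture_loglik,
)

__all__ = [
    "MixtureFit",
    "ConstraintReport",
    "init_mixing",
    "fit_mixtwice",
    "verify_constraints",
    "oracle_fit_mesh",
]

_FEAS_TOL = 1e-8
_DENSITY_FLOOR = 1e-300  # guards log(0) while the solver probes the boundary


@dataclass
class MixtureFit:
    """Result of the constrained MLE.

    Attributes
    ----------
    g, h : ndarray
        Estimated mixing probabilities over the effect / variance grids.
    loglik : float
        Attained log-likelihood (over the units used for fitting).
    converged : bool
        True iff the relative objective change fell below ``tol`` before
        ``max_outer`` outer iterations were exhausted.
    n_outer : int
        Outer iterations used.
    constraint_violation : float
        Maximum violation over simplex and ordering constraints at return.
    subsample_indices : ndarray or None
        Unit subset used in the optimization, when subsampling was on.
    """

    g: np.ndarray
    h: np.ndarray
    loglik: float
    converged: bool
    n_outer: int
    constraint_violation: float
    egrid: EffectGrid
    vgrid: VarianceGrid
    subsample_indices: Optional[np.ndarray] = None
    message: str = ""


@dataclass(frozen=True)
class ConstraintReport:
    max_simplex_violation: float
    max_order_violation: float
    ok: bool


def init_mixing(egrid: EffectGrid, vgrid: VarianceGrid):
    """Deterministic uniform/uniform starting point (feasible: the ordering
    constraints hold with equalities)."""
    n_a = egrid.n_points
    n_b = vgrid.L
    return np.full(n_a, 1.0 / n_a), np.full(n_b, 1.0 / n_b)


def _order_matrix(K: int, n_a: int) -> np.ndarray:
    """Rows A such that A @ g >= 0 encodes unimodality about index K."""
    rows = []
    for j in range(K, 2 * K):  # right arm: g_j - g_{j+1} >= 0
        r = np.zeros(n_a)
        r[j], r[j + 1] = 1.0, -1.0
        rows.append(r)
    for j in range(0, K):  # left arm: g_{j+1} - g_j >= 0
        r = np.zeros(n_a)
        r[j + 1], r[j] = 1.0, -1.0
        rows.append(r)
    return np.array(rows) if rows else np.zeros((0, n_a))


def _violations(g: np.ndarray, h: np.ndarray, K: int):
    simplex = max(
        abs(float(g.sum()) - 1.0),
        abs(float(h.sum()) - 1.0),
        max(0.0, -float(g.min(initial=0.0))),
        max(0.0, -float(h.min(initial=0.0))),
    )
    A = _order_matrix(K, len(g))
    order = float(np.max(np.maximum(0.0, -(A @ g)))) if len(A) else 0.0
    return simplex, order


def _project_feasible(g: np.ndarray, h: np.ndarray, K: int):
    """Restore exact feasibility; perturbation is bounded by the violation."""
    g = np.maximum(g, 0.0)
    h = np.maximum(h, 0.0)
    # sweep outwards from the mode so each arm is monotone
    for j in range(K, 2 * K):
        if g[j + 1] > g[j]:
            g[j + 1] = g[j]
    for j in range(K, 0, -1):
        if g[j - 1] > g[j]:
            g[j - 1] = g[j]
    gs, hs = g.sum(), h.sum()
    if gs <= 0 or hs <= 0:  # pathological; fall back to uniform
        g = np.full_like(g, 1.0 / len(g))
        h = np.full_like(h, 1.0 / len(h))
    else:
        g = g / gs
        h = h / hs
    return g, h


def verify_constraints(fit: MixtureFit, tol: float = _FEAS_TOL) -> ConstraintReport:
    """Exact arithmetic check of simplex and unimodality constraints."""
    simplex, order = _violations(np.asarray(fit.g, float), np.asarray(fit.h, float), fit.egrid.K)
    return ConstraintReport(
        max_simplex_violation=simplex,
        max_order_violation=order,
        ok=(simplex <= tol and order <= tol),
    )


def _make_objective(comp: ComponentLogLik):
    """Negative log-likelihood and gradient on z = concat(g, h), with the
    component tensor exponentiated once (per-unit max factored out)."""
    M = np.max(comp.entries, axis=(1, 2))
    Q = np.exp(comp.entries - M[:, None, None])
    n_a = comp.entries.shape[1]
    M_sum = float(np.sum(M))

    def negloglik_grad(z):
        g, h = z[:n_a], z[n_a:]
        Qh = Q @ h
        f = Qh @ g
        f_safe = np.maximum(f, _DENSITY_FLOOR)
        val = -(np.sum(np.log(f_safe)) + M_sum)
        inv_f = 1.0 / f_safe
        grad_g = -(Qh.T @ inv_f)
        grad_h = -(np.tensordot(Q, g, axes=([1], [0])).T @ inv_f)
        return val, np.concatenate([grad_g, grad_h])

    return negloglik_grad, Q, M_sum


def _pava(y: np.ndarray, increasing: bool) -> np.ndarray:
    """Unit-weight pool-adjacent-violators (least-squares isotonic fit)."""
    if not increasing:
        return _pava(y[::-1], True)[::-1]
    vals = []
    counts = []
    for v in y:
        vals.append(float(v))
        counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            tot = vals[-1] * counts[-1] + vals[-2] * counts[-2]
            cnt = counts[-1] + counts[-2]
            vals.pop(); counts.pop()
            vals[-1] = tot / cnt
            counts[-1] = cnt
    return np.repeat(vals, counts)


def _unimodal_isotonic(c: np.ndarray, K: int, n_iter: int = 60) -> np.ndarray:
    """Least-squares projection of c onto the unimodal cone with mode at
    index K (Dykstra's alternating projections between the two chain
    cones, each solved exactly by PAVA on the arm including the mode)."""
    x = c.astype(float).copy()
    p = np.zeros_like(x)
    q = np.zeros_like(x)
    for _ in range(n_iter):
        y = x + p
        z = y.copy()
        z[: K + 1] = _pava(y[: K + 1], increasing=True)
        p = y - z
        y2 = z + q
        x_new = y2.copy()
        x_new[K:] = _pava(y2[K:], increasing=False)
        q = y2 - x_new
        if np.max(np.abs(x_new - x)) < 1e-12:
            x = x_new
            break
        x = x_new
    return x


def _em_warm_start(Q: np.ndarray, g: np.ndarray, h: np.ndarray, K: int,
                   n_iter: int = 200, rtol: float = 1e-9):
    """Multiplicative EM updates with an order-restricted M-step for g.

    The unconstrained M-step weights are the average responsibilities; the
    unimodal M-step for g is their isotonic regression under the unimodal
    partial order (exact for the multinomial complete-data likelihood), so
    every iteration is feasible and the observed log-likelihood is
    monotone up to the projection tolerance.  Cheap per iteration; used to
    reach the neighborhood of the optimum before SLSQP polishes.
    """
    m = Q.shape[0]
    prev = -np.inf
    for it in range(n_iter):
        Qh = Q @ h  # (m, n_a)
        f = np.maximum(Qh @ g, _DENSITY_FLOOR)
        inv_f = 1.0 / f
        # E-step responsibilities, aggregated analytically
        c_g = g * (Qh.T @ inv_f) / m
        c_h = h * (np.tensordot(Q, g, axes=([1], [0])).T @ inv_f) / m
        g = _unimodal_isotonic(c_g, K)
        g = np.maximum(g, 0.0)
        g /= g.sum()
        h = np.maximum(c_h, 0.0)
        h /= h.sum()
        ll = float(np.sum(np.log(f)))
        if it > 0 and abs(ll - prev) <= rtol * (1.0 + abs(prev)):
            break
        prev = ll
    return g, h


def fit_mixtwice(
    stats: SummaryStats,
    K: int = 15,
    L: int = 10,
    mode: float = 0.0,
    *,
    tol: float = 1e-8,
    max_outer: int = 100,
    subsample_fraction: float = 1.0,
    seed: Optional[int] = None,
    egrid: Optional[EffectGrid] = None,
    vgrid: Optional[VarianceGrid] = None,
) -> MixtureFit:
    """Fit the two mixing distributions by constrained maximum likelihood.

    Parameters
    ----------
    stats : SummaryStats
        Per-unit effects, squared standard errors and shared df.
    K, L : int
        Half-width of the effect grid (2K+1 points) and size of the
        variance grid.  Grids are always built from the *full* data so a
        subsampled fit remains usable for posterior evaluation of every
        unit; pass ``egrid``/``vgrid`` to override.
    mode : float
        Presumed mode of the effect distribution (the null value).
    tol : float
        Convergence threshold on the relative objective change across an
        outer iteration.
    max_outer : int
        Cap on outer iterations.
    subsample_fraction : float
        If < 1, the likelihood is summed over a seeded uniform random
        subset of ``ceil(fraction * m)`` units (a computational shortcut
        for very large m); ``seed`` is then mandatory.

    Returns
    -------
    MixtureFit
        Feasible (within 1e-8) estimates with diagnostics.  Solver
        failures are reported via ``converged=False``, never raised.
    """
    if not isinstance(stats, SummaryStats):
        stats = SummaryStats.from_arrays(**stats) if isinstance(stats, dict) else stats
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if egrid is None:
        egrid = build_effect_grid(stats.x, K=K, mode=mode)
    if vgrid is None:
        vgrid = build_variance_grid(stats.s2, L=L)

    subsample_indices = None
    fit_stats = stats
    if subsample_fraction < 1.0:
        if seed is None:
            raise ValueError("seed is required when subsample_fraction < 1")
        rng = np.random.default_rng(seed)
        n_sub = int(np.ceil(subsample_fraction * stats.m))
        subsample_indices = np.sort(
            rng.choice(stats.m, size=n_sub, replace=False)
        )
        fit_stats = SummaryStats(
            unit_ids=stats.unit_ids[subsample_indices],
            x=stats.x[subsample_indices],
            s2=stats.s2[subsample_indices],
            df=stats.df,
        )

    comp = component_loglik(fit_stats, egrid, vgrid)
    negll, Q, _ = _make_objective(comp)
    n_a, n_b = egrid.n_points, vgrid.L
    K_eff = egrid.K

    A = _order_matrix(K_eff, n_a)
    A_full = np.hstack([A, np.zeros((A.shape[0], n_b))])
    E = np.zeros((2, n_a + n_b))
    E[0, :n_a] = 1.0
    E[1, n_a:] = 1.0
    constraints = [
        {"type": "eq", "fun": lambda z: E @ z - 1.0, "jac": lambda z: E},
    ]
    if len(A_full):
        constraints.append(
            {"type": "ineq", "fun": lambda z: A_full @ z, "jac": lambda z: A_full}
        )
    bounds = [(0.0, 1.0)] * (n_a + n_b)

    g0, h0 = init_mixing(egrid, vgrid)
    z0 = np.concatenate([g0, h0])
    best_val = negll(z0)[0]
    best_z = z0.copy()

    # EM warm start: monotone, boundary-friendly, cheap per iteration
    g_w, h_w = _em_warm_start(Q, g0.copy(), h0.copy(), K_eff)
    z = np.concatenate([g_w, h_w])
    warm_val = negll(z)[0]
    if warm_val < best_val:
        best_val, best_z = warm_val, z.copy()
    else:
        z = z0.copy()

    converged = False
    message = ""
    n_outer = 0
    prev_val = best_val
    for n_outer in range(1, max_outer + 1):
        # inner stop a notch tighter than the outer convergence criterion
        ftol = max(1e-13, 0.05 * tol * (1.0 + abs(prev_val)))
        try:
            res = minimize(
                negll,
                z,
                jac=True,
                method="SLSQP",
                bounds=bounds,
                constraints=constraints,
                options={"maxiter": 200, "ftol": ftol},
            )
        except Exception as exc:  # report, never throw
            message = f"solver failure: {exc}"
            break
        z = np.clip(res.x, 0.0, 1.0)
        cur_val = negll(z)[0]
        if cur_val < best_val:
            best_val, best_z = cur_val, z.copy()
        rel_change = abs(prev_val - cur_val) / (1.0 + abs(prev_val))
        if rel_change < tol:
            converged = True
            message = res.message
            break
        prev_val = cur_val
        message = res.message

    g, h = best_z[:n_a].copy(), best_z[n_a:].copy()
    g, h = _project_feasible(g, h, K_eff)
    loglik, _, _ = mixture_loglik(g, h, comp)
    # the projection must never cost likelihood relative to the start point
    ll0, _, _ = mixture_loglik(g0, h0, comp)
    if loglik < ll0:
        g, h, loglik = g0, h0, ll0
        converged = False
        message = message or "projected solution worse than uniform start"
    simplex, order = _violations(g, h, K_eff)
    return MixtureFit(
        g=g,
        h=h,
        loglik=float(loglik),
        converged=converged,
        n_outer=n_outer,
        constraint_violation=max(simplex, order),
        egrid=egrid,
        vgrid=vgrid,
        subsample_indices=subsample_indices,
        message=str(message),
    )


def _simplex_mesh(n_parts: int, n_steps: int) -> np.ndarray:
    """All probability vectors with entries in multiples of 1/n_steps."""
    out = np.empty((comb(n_steps + n_parts - 1, n_parts - 1), n_parts))
    for row, cuts in enumerate(combinations(range(n_steps + n_parts - 1), n_parts - 1)):
        prev = -1
        for j, c in enumerate(cuts):
            out[row, j] = c - prev - 1
            prev = c
        out[row, n_parts - 1] = n_steps + n_parts - 2 - prev
    return out / n_steps


def _is_unimodal(G: np.ndarray, K: int) -> np.ndarray:
    ok = np.ones(len(G), dtype=bool)
    for j in range(K, 2 * K):
        ok &= G[:, j] >= G[:, j + 1]
    for j in range(0, K):
        ok &= G[:, j + 1] >= G[:, j]
    return ok


def oracle_fit_mesh(
    stats: SummaryStats,
    egrid: EffectGrid,
    vgrid: VarianceGrid,
    step: float = 0.01,
    max_candidates: int = 2_000_000,
) -> MixtureFit:
    """Brute-force reference optimizer on a simplex mesh (test oracle).

    Enumerates every probability vector whose entries are multiples of
    ``step`` on both simplices, keeps only unimodal ``g``, and returns the
    mesh point with the highest mixture log-likelihood.  Only intended for
    tiny grids; refuses combinatorially large requests.
    """
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-12:
        raise ValueError("step must divide 1 exactly")
    n_a, n_b = egrid.n_points, vgrid.L
    if n_a > 5 or n_b > 2:
        raise ValueError("oracle_fit_mesh only supports <=5 effect and <=2 variance points")
    n_g = comb(n_steps + n_a - 1, n_a - 1)
    n_h = comb(n_steps + n_b - 1, n_b - 1)
    if n_g * n_h > max_candidates:
        raise ValueError(
            f"mesh too large ({n_g} x {n_h} candidates); refuse to enumerate"
        )

    G = _simplex_mesh(n_a, n_steps)
    G = G[_is_unimodal(G, egrid.K)]
    H = _simplex_mesh(n_b, n_steps) if n_b > 1 else np.ones((1, 1))

    comp = component_loglik(stats, egrid, vgrid)
    M = np.max(comp.entries, axis=(1, 2))
    Q = np.exp(comp.entries - M[:, None, None])
    M_sum = float(np.sum(M))

    best = (-np.inf, None, None)
    with np.errstate(divide="ignore"):
        for h in H:
            Qh = Q @ h  # (m, n_a)
            F = Qh @ G.T  # (m, n_G)
            ll = np.sum(np.log(F), axis=0) + M_sum
            j = int(np.argmax(ll))
            if ll[j] > best[0]:
                best = (float(ll[j]), G[j].copy(), h.copy())

    ll_best, g_best, h_best = best
    simplex, order = _violations(g_best, h_best, egrid.K)
    return MixtureFit(
        g=g_best,
        h=h_best,
        loglik=ll_best,
        converged=True,
        n_outer=0,
        constraint_violation=max(simplex, order),
        egrid=egrid,
        vgrid=vgrid,
        message="mesh oracle",
    )
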