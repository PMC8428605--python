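"""Grids, component densities and the mixture log-likelihood.

The sampling model treats each testing unit i (a peptide, gene, probe, ...)
as contributing an estimated effect ``x_i`` and a squared standard error
``s2_i``.  Given the latent effect ``theta_i`` and latent variance
``sigma2_i``,

* ``x_i ~ Normal(theta_i, sigma2_i)``,
* ``nu * s2_i / sigma2_i ~ chi-square(nu)`` with design-determined degrees
  of freedom ``nu`` shared across units,

and the latent pair is drawn from a product of two discrete mixing
distributions: ``g`` on a regular, symmetric effect grid
``a_{-K}, ..., a_0, ..., a_K`` (mode ``a_0``) and ``h`` on a regular
positive variance grid ``b_1, ..., b_L``.  This module holds the grid
constructors, the two component log-densities, their per-unit table, and
the stabilized mixture log-likelihood with exact gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "DegenerateDataError",
    "SummaryStats",
    "EffectGrid",
    "VarianceGrid",
    "ComponentLogLik",
    "build_effect_grid",
    "build_variance_grid",
    "scaled_chisq_logdensity",
    "normal_component_logdensity",
    "component_loglik",
    "mixture_loglik",
]

_GRID_RTOL = 1e-9  # relative tolerance for "regular grid" spacing checks


class DegenerateDataError(ValueError):
    """Raised when input data are degenerate (e.g. zero spread)."""


def _as_1d_float(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 1:
        out = out.reshape(-1)
    if out.size == 0:
        raise ValueError(f"{name} must be nonempty")
    return out


@dataclass(frozen=True)
class SummaryStats:
    """Per-unit summary statistics: the method's entire data interface.

    Parameters
    ----------
    unit_ids : array of str
        Opaque unit labels.
    x : array of float
        Estimated effects, one per unit.
    s2 : array of float
        Squared standard errors, strictly positive.
    df : float
        Degrees of freedom ``nu`` of the chi-square model for ``s2``,
        shared by every unit (design-based; e.g. total samples minus two).
    """

    unit_ids: np.ndarray
    x: np.ndarray
    s2: np.ndarray
    df: float

    def __post_init__(self) -> None:
        x = _as_1d_float(self.x, "x")
        s2 = _as_1d_float(self.s2, "s2")
        ids = np.asarray(self.unit_ids, dtype=object).reshape(-1)
        if not (len(ids) == len(x) == len(s2)):
            raise ValueError(
                f"unit_ids, x, s2 must have equal length; got "
                f"{len(ids)}, {len(x)}, {len(s2)}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("all effect estimates x must be finite")
        if not np.all(np.isfinite(s2)) or np.any(s2 <= 0):
            raise ValueError("all squared standard errors s2 must be finite and > 0")
        if np.ndim(self.df) != 0:
            raise ValueError(
                "df must be a single scalar shared by all units "
                "(per-unit df is rejected, not averaged)"
            )
        df = float(self.df)
        if not np.isfinite(df):
            raise ValueError("df must be finite")
        if df < 1:
            raise ValueError(f"df must be >= 1, got {df}")
        object.__setattr__(self, "unit_ids", ids)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "s2", s2)
        object.__setattr__(self, "df", df)

    @property
    def m(self) -> int:
        """Number of testing units."""
        return len(self.x)

    @classmethod
    def from_arrays(cls, x, s2, df, unit_ids=None) -> "SummaryStats":
        x = _as_1d_float(x, "x")
        if unit_ids is None:
            unit_ids = np.array([f"unit{i}" for i in range(len(x))], dtype=object)
        return cls(unit_ids=np.asarray(unit_ids, dtype=object), x=x, s2=s2, df=df)


def _check_regular(values: np.ndarray, name: str) -> float:
    diffs = np.diff(values)
    if np.any(diffs <= 0):
        raise ValueError(f"{name} grid values must be strictly increasing")
    spacing = float(diffs[0]) if diffs.size else 0.0
    if diffs.size and not np.allclose(diffs, spacing, rtol=_GRID_RTOL, atol=0.0):
        raise ValueError(f"{name} grid must be regular (equal spacing)")
    return spacing


@dataclass(frozen=True)
class EffectGrid:
    """Regular symmetric support ``a_{-K}..a_K`` for the effect mixing
    distribution; ``a_0`` (the middle point) is the presumed mode."""

    values: np.ndarray
    K: int
    mode_value: float = 0.0

    def __post_init__(self) -> None:
        values = _as_1d_float(self.values, "effect grid values")
        K = int(self.K)
        if K < 1:
            raise ValueError("K must be >= 1")
        if len(values) != 2 * K + 1:
            raise ValueError(
                f"effect grid must have exactly 2K+1 = {2 * K + 1} points, "
                f"got {len(values)}"
            )
        _check_regular(values, "effect")
        if values[K] != float(self.mode_value):
            raise ValueError("middle grid point must equal the mode exactly")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "mode_value", float(self.mode_value))

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def mode_index(self) -> int:
        return self.K

    @property
    def n_points(self) -> int:
        return 2 * self.K + 1


@dataclass(frozen=True)
class VarianceGrid:
    """Regular positive support ``b_1..b_L`` for the variance mixing
    distribution."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = _as_1d_float(self.values, "variance grid values")
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            raise ValueError("variance grid values must be finite and > 0")
        if len(values) > 1:
            _check_regular(values, "variance")
        object.__setattr__(self, "values", values)

    @property
    def L(self) -> int:
        return len(self.values)


def build_effect_grid(x, K: int = 15, mode: float = 0.0) -> EffectGrid:
    """Regular grid of 2K+1 effect values symmetric about ``mode``.

    The half-width is ``max_i |x_i - mode|`` so every observed estimate lies
    inside the support.  Raises :class:`DegenerateDataError` if all estimates
    equal the mode (zero half-width).
    """
    x = _as_1d_float(x, "x")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite to build the effect grid")
    K = int(K)
    if K < 1:
        raise ValueError("K must be >= 1")
    half_width = float(np.max(np.abs(x - mode)))
    if half_width == 0.0:
        raise DegenerateDataError(
            "cannot build effect grid: every estimate equals the mode "
            "(zero half-width)"
        )
    values = mode + np.linspace(-half_width, half_width, 2 * K + 1)
    values[K] = mode  # exact mode, immune to rounding
    return EffectGrid(values=values, K=K, mode_value=float(mode))


def build_variance_grid(s2, L: int = 10) -> VarianceGrid:
    """Regular grid of L values spanning the observed range of ``s2``.

    A degenerate (constant) input is padded to ±5% of the common value; with
    ``L = 1`` the single point is the midpoint of the span.
    """
    s2 = _as_1d_float(s2, "s2")
    if np.any(s2 <= 0) or not np.all(np.isfinite(s2)):
        raise ValueError("s2 must be finite and > 0 to build the variance grid")
    L = int(L)
    if L < 1:
        raise ValueError("L must be >= 1")
    lo, hi = float(np.min(s2)), float(np.max(s2))
    if lo == hi:
        lo, hi = 0.95 * lo, 1.05 * hi
    if L == 1:
        return VarianceGrid(values=np.array([(lo + hi) / 2.0]))
    return VarianceGrid(values=np.linspace(lo, hi, L))


def scaled_chisq_logdensity(s2, b, df):
    """Log-density of the squared standard error given latent variance b.

    With ``nu * s2 / b ~ chi-square(nu)``, the density of ``s2`` is
    ``(nu/b) * f_chi2(nu * s2 / b; nu)``.  Vectorized over any broadcastable
    combination of arguments; may return ``-inf`` where the density is 0.
    """
    s2 = np.asarray(s2, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("s2 must be > 0")
    if np.any(b <= 0):
        raise ValueError("variance grid point b must be > 0")
    if np.any(np.asarray(df) < 1):
        raise ValueError("df must be >= 1")
    y = df * s2 / b
    return np.log(df / b) + _stats.chi2.logpdf(y, df)


def normal_component_logdensity(x, a, b):
    """Log-density of the effect estimate given latent effect a, variance b:
    ``log phi((x - a)/sqrt(b)) - log sqrt(b)``.  Finite for finite inputs."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("variance grid point b must be > 0")
    with np.errstate(over="ignore"):  # extreme deviations overflow to -inf
        return -0.5 * (np.log(2.0 * np.pi * b) + (x - a) ** 2 / b)


@dataclass(frozen=True)
class ComponentLogLik:
    """Per-unit table of component log-likelihoods over the grid product.

    ``entries[i, k, l]`` is the log joint density of ``(x_i, s2_i)`` at
    ``theta = a_k``, ``sigma2 = b_l``; ``chisq_part[i, l]`` caches the
    (effect-independent) squared-standard-error factor.
    """

    entries: np.ndarray  # (m, 2K+1, L)
    chisq_part: np.ndarray  # (m, L)
    egrid: EffectGrid
    vgrid: VarianceGrid

    @property
    def m(self) -> int:
        return self.entries.shape[0]


def component_loglik(
    stats: SummaryStats, egrid: EffectGrid, vgrid: VarianceGrid
) -> ComponentLogLik:
    """Evaluate the component log-densities for every (unit, a_k, b_l)."""
    a = egrid.values  # (2K+1,)
    b = vgrid.values  # (L,)
    # chi-square factor depends on (i, l) only: computed once and broadcast.
    chisq_part = scaled_chisq_logdensity(stats.s2[:, None], b[None, :], stats.df)
    normal_part = normal_component_logdensity(
        stats.x[:, None, None], a[None, :, None], b[None, None, :]
    )
    entries = normal_part + chisq_part[:, None, :]
    return ComponentLogLik(
        entries=entries, chisq_part=chisq_part, egrid=egrid, vgrid=vgrid
    )


def _check_prob_vector(v, n: int, name: str, tol: float) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {v.shape}")
    if np.any(v < 0):
        raise ValueError(f"{name} must be nonnegative")
    if abs(v.sum() - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 within {tol}")
    return v


def mixture_loglik(g, h, comp: ComponentLogLik, validate: bool = True):
    """Mixture log-likelihood and its exact gradient.

    Computes ``sum_i log sum_{k,l} g_k h_l p_i(k,l)`` with per-unit
    log-sum-exp stabilization (the per-unit maximum log entry is factored
    out).  Returns ``(loglik, grad_g, grad_h)``.  ``loglik`` is ``-inf``
    only if some unit receives zero total mixture density.

    With ``validate=False`` the simplex check is skipped, so the objective
    can be probed slightly off-simplex (e.g. by finite differences).
    """
    m, n_a, n_b = comp.entries.shape
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != (n_a,) or h.shape != (n_b,):
        raise ValueError(
            f"dimension mismatch: need g of shape ({n_a},) and h of shape "
            f"({n_b},), got {g.shape} and {h.shape}"
        )
    if validate:
        _check_prob_vector(g, n_a, "g", 1e-8)
        _check_prob_vector(h, n_b, "h", 1e-8)

    M = np.max(comp.entries, axis=(1, 2))  # (m,) finite: normal part is finite
    Q = np.exp(comp.entries - M[:, None, None])  # (m, 2K+1, L), max 1 per unit
    Qh = Q @ h  # (m, 2K+1)
    f = Qh @ g  # (m,) mixture density / exp(M)
    with np.errstate(divide="ignore"):
        log_f = np.log(f)
    loglik = float(np.sum(log_f) + np.sum(M))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_f = np.where(f > 0, 1.0 / f, np.inf)
    grad_g = Qh.T @ inv_f  # (2K+1,)
    grad_h = np.einsum("ikl,k,i->l", Q, g, inv_f)
    return loglik, grad_g, grad_h
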