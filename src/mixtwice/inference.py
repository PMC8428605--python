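"""Posterior effect distributions, lfdr/lfsr statistics and discovery lists.

Given fitted mixing distributions ``(g, h)``, each unit's posterior over the
effect grid is

    P(theta_i = a_k | x_i, s2_i)  proportional to  g_k * sum_l h_l p_i(k, l),

normalized over the grid.  The local false discovery rate is the posterior
mass at the mode (the null value); the local false sign rate is the smaller
of the posterior probabilities of ``theta <= a_0`` and ``theta >= a_0``
(both cumulative sums include the mode mass, hence lfsr >= lfdr always).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .fit import MixtureFit
from .model_core import SummaryStats, component_loglik

__all__ = [
    "PosteriorTable",
    "DiscoveryList",
    "posterior_effects",
    "discovery_list",
    "estimate_pi0",
    "overlap_metrics",
]


@dataclass(frozen=True)
class PosteriorTable:
    """Per-unit posterior over the effect grid plus lfdr/lfsr statistics."""

    unit_ids: np.ndarray
    grid_values: np.ndarray  # effect grid (2K+1,)
    mode_index: int
    P: np.ndarray  # (m, 2K+1), rows sum to 1
    lfdr: np.ndarray
    lfsr: np.ndarray

    @property
    def m(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class DiscoveryList:
    """Units whose statistic falls at or below the threshold.

    ``fdr_estimate`` is the mean lfdr over the list, a convenient estimate
    of the expected false-discovery rate within it (None for empty lists).
    """

    indices: np.ndarray  # positions into the posterior table
    unit_ids: np.ndarray
    threshold: float
    statistic: str
    fdr_estimate: Optional[float]

    @property
    def size(self) -> int:
        return len(self.indices)


def posterior_effects(fit: MixtureFit, stats: SummaryStats) -> PosteriorTable:
    """Posterior effect distribution, lfdr and lfsr for every unit.

    Computed in log space; raises if some unit has zero total posterior
    density (which names the offending unit).
    """
    comp = component_loglik(stats, fit.egrid, fit.vgrid)
    with np.errstate(divide="ignore"):
        log_g = np.log(fit.g)
        log_h = np.log(fit.h)
    # marginalize the variance layer, then weight by g
    log_like_k = logsumexp(comp.entries + log_h[None, None, :], axis=2)  # (m, 2K+1)
    log_post = log_g[None, :] + log_like_k
    norm = logsumexp(log_post, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        ids = ", ".join(map(str, stats.unit_ids[bad][:5]))
        raise ValueError(f"zero total posterior density for unit(s): {ids}")
    P = np.exp(log_post - norm[:, None])
    k0 = fit.egrid.mode_index
    lfdr = P[:, k0].copy()
    lfsr = np.minimum(P[:, : k0 + 1].sum(axis=1), P[:, k0:].sum(axis=1))
    # guard against rounding pushing lfsr a hair below lfdr
    lfsr = np.clip(lfsr, lfdr, None)
    return PosteriorTable(
        unit_ids=stats.unit_ids,
        grid_values=fit.egrid.values,
        mode_index=k0,
        P=P,
        lfdr=lfdr,
        lfsr=lfsr,
    )


def discovery_list(
    post: PosteriorTable, alpha: float, statistic: str = "lfdr"
) -> DiscoveryList:
    """All units with ``statistic <= alpha`` (deterministic threshold rule)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if statistic not in ("lfdr", "lfsr"):
        raise ValueError("statistic must be 'lfdr' or 'lfsr'")
    values = post.lfdr if statistic == "lfdr" else post.lfsr
    idx = np.flatnonzero(values <= alpha)
    fdr_est = float(np.mean(post.lfdr[idx])) if len(idx) else None
    return DiscoveryList(
        indices=idx,
        unit_ids=post.unit_ids[idx],
        threshold=float(alpha),
        statistic=statistic,
        fdr_estimate=fdr_est,
    )


def estimate_pi0(fit: MixtureFit) -> float:
    """Estimated null proportion: the mixing mass g at the grid mode."""
    return float(fit.g[fit.egrid.mode_index])


def overlap_metrics(list_a: DiscoveryList, list_b: DiscoveryList) -> dict:
    """Cross-study reproducibility: intersection size and common fraction
    ``|A & B| / |A | B|`` (NaN when both lists are empty)."""
    a = set(map(str, list_a.unit_ids))
    b = set(map(str, list_b.unit_ids))
    n_common = len(a & b)
    n_union = len(a | b)
    common_fraction = (n_common / n_union) if n_union else float("nan")
    return {"n_common": n_common, "common_fraction": common_fraction}
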