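"""Generative scenarios and the operating-characteristic harness.

Effects are drawn from ``pi0 * delta_0 + (1 - pi0) * g_alt`` with the named
alternative shapes of the adaptive-shrinkage literature (spiky, near-normal,
flat-top, big-variance, bimodal); latent variances come from a point mass, a
two-point mixture or an inverse-gamma.  Each unit then yields Gaussian
two-group samples, summarized exactly as real data would be.  The harness
repeats simulate -> fit -> infer, scoring null-proportion recovery, the
1-Wasserstein error of the estimated effect distribution, and the realized
false discovery proportion of lfdr-thresholded lists, with replicate-level
results aggregated inside the four pi0 strata
[0.5, 0.625], [0.625, 0.75], [0.75, 0.875], [0.875, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .fit import MixtureFit, fit_mixtwice
from .inference import DiscoveryList, discovery_list, estimate_pi0, posterior_effects
from .model_core import SummaryStats
from .summarize import GroupedMatrix, two_group_summary

__all__ = [
    "PointMass",
    "TwoPoint",
    "InverseGamma",
    "ScenarioSpec",
    "SimulatedStudy",
    "SCENARIO_SHAPES",
    "make_scenario",
    "sample_effects",
    "sample_variances",
    "simulate_dataset",
    "empirical_fdp",
    "wasserstein1",
    "true_effect_distribution",
    "run_operating_characteristics",
    "aggregate_by_pi0_strata",
    "PI0_STRATA",
]

PI0_STRATA = ((0.5, 0.625), (0.625, 0.75), (0.75, 0.875), (0.875, 1.0))


# ---------------------------------------------------------------------------
# variance models

@dataclass(frozen=True)
class PointMass:
    """Degenerate variance distribution: every unit shares one variance."""

    v: float = 1.0

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("point-mass variance must be > 0")

    def sample(self, m: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(m, float(self.v))


@dataclass(frozen=True)
class TwoPoint:
    """Two-valued variance mixture: v1 w.p. w, else v2."""

    v1: float = 0.5
    v2: float = 2.0
    w: float = 0.5

    def __post_init__(self):
        if self.v1 <= 0 or self.v2 <= 0:
            raise ValueError("two-point variances must be > 0")
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("weight w must be in [0, 1]")

    def sample(self, m: int, rng: np.random.Generator) -> np.ndarray:
        pick = rng.random(m) < self.w
        return np.where(pick, float(self.v1), float(self.v2))


@dataclass(frozen=True)
class InverseGamma:
    """Continuous variance model; mean = scale / (shape - 1) for shape > 1."""

    shape: float = 5.0
    scale: float = 4.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("inverse-gamma parameters must be > 0")

    def sample(self, m: int, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(
            _stats.invgamma.rvs(self.shape, scale=self.scale, size=m, random_state=rng)
        )


VarianceModel = Union[PointMass, TwoPoint, InverseGamma]


# ---------------------------------------------------------------------------
# effect scenarios

# Named alternative shapes, parameterized as normal mixtures
# (weight, center, sd); weights sum to 1.  These follow the standard
# adaptive-shrinkage benchmark shapes and are overridable per scenario.
SCENARIO_SHAPES = {
    "spiky": [(0.4, 0.0, 0.25), (0.2, 0.0, 0.5), (0.2, 0.0, 1.0), (0.2, 0.0, 2.0)],
    "near_normal": [(2.0 / 3.0, 0.0, 1.0), (1.0 / 3.0, 0.0, 2.0)],
    "flattop": [(1.0 / 7.0, mu, 0.5) for mu in (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)],
    "big_variance": [(1.0, 0.0, 4.0)],
    "bimodal": [(0.5, -2.0, 1.0), (0.5, 2.0, 1.0)],
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative configuration for one synthetic study.

    ``pi0=None`` means the harness draws a fresh pi0 ~ Uniform[0.5, 1] per
    replicate (the benchmark's default regime).
    """

    name: str
    pi0: Optional[float] = None
    alt_components: Sequence[tuple] = ()
    variance_model: VarianceModel = field(default_factory=PointMass)
    n_per_group: int = 10
    m: int = 1000

    def __post_init__(self):
        comps = [tuple(map(float, c)) for c in self.alt_components]
        if not comps:
            raise ValueError("alt_components must be nonempty")
        w = np.array([c[0] for c in comps])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("component weights must be >= 0 and sum to 1")
        if any(c[2] <= 0 for c in comps):
            raise ValueError("component sds must be > 0")
        if self.pi0 is not None and not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must be in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        object.__setattr__(self, "alt_components", tuple(comps))


def make_scenario(
    name: str,
    pi0: Optional[float] = None,
    variance_model: Optional[VarianceModel] = None,
    n_per_group: int = 10,
    m: int = 1000,
) -> ScenarioSpec:
    """Build a named scenario with its standard alternative shape."""
    if name not in SCENARIO_SHAPES:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIO_SHAPES)}")
    return ScenarioSpec(
        name=name,
        pi0=pi0,
        alt_components=SCENARIO_SHAPES[name],
        variance_model=variance_model if variance_model is not None else PointMass(1.0),
        n_per_group=n_per_group,
        m=m,
    )


def sample_effects(spec: ScenarioSpec, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw latent effects: 0 with probability pi0, else from g_alt."""
    pi0 = spec.pi0 if spec.pi0 is not None else 1.0
    theta = np.zeros(m)
    alt = rng.random(m) >= pi0
    n_alt = int(alt.sum())
    if n_alt:
        w = np.array([c[0] for c in spec.alt_components])
        centers = np.array([c[1] for c in spec.alt_components])
        sds = np.array([c[2] for c in spec.alt_components])
        comp = rng.choice(len(w), size=n_alt, p=w)
        theta[alt] = rng.normal(centers[comp], sds[comp])
    return theta


def sample_variances(
    model: VarianceModel, m: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. latent observation variances from the named model."""
    return model.sample(m, rng)


@dataclass(frozen=True)
class SimulatedStudy:
    """A realized synthetic dataset with its ground truth."""

    theta: np.ndarray
    sigma2: np.ndarray
    gm: GroupedMatrix
    stats: SummaryStats
    seed: int
    pi0: float
    spec: ScenarioSpec


def simulate_dataset(spec: ScenarioSpec, seed: int, pi0: Optional[float] = None) -> SimulatedStudy:
    """Simulate one two-group study under the scenario.

    Group 1 (reference) observations are Normal(0, sigma2_i), group 2 (case)
    Normal(theta_i, sigma2_i), ``n_per_group`` each; summaries come from
    :func:`two_group_summary` so the synthetic pipeline matches the real one
    exactly.  Fully determined by ``seed``.
    """
    if pi0 is None:
        if spec.pi0 is None:
            raise ValueError("pi0 must be given either in the spec or as an argument")
        pi0 = spec.pi0
    rng = np.random.default_rng(seed)
    eff_spec = spec if spec.pi0 == pi0 else ScenarioSpec(
        name=spec.name,
        pi0=pi0,
        alt_components=spec.alt_components,
        variance_model=spec.variance_model,
        n_per_group=spec.n_per_group,
        m=spec.m,
    )
    theta = sample_effects(eff_spec, spec.m, rng)
    sigma2 = sample_variances(spec.variance_model, spec.m, rng)
    n = spec.n_per_group
    sd = np.sqrt(sigma2)[:, None]
    y1 = rng.normal(0.0, sd, size=(spec.m, n))
    y2 = rng.normal(theta[:, None], sd, size=(spec.m, n))
    gm = GroupedMatrix(
        values=np.hstack([y1, y2]),
        labels=np.array(["control"] * n + ["case"] * n, dtype=object),
        reference="control",
    )
    stats = two_group_summary(gm)
    return SimulatedStudy(
        theta=theta, sigma2=sigma2, gm=gm, stats=stats, seed=int(seed),
        pi0=float(pi0), spec=eff_spec,
    )


def empirical_fdp(dlist: DiscoveryList, theta: np.ndarray) -> float:
    """False discovery proportion of a list against known effects
    (0 for an empty list by convention)."""
    theta = np.asarray(theta, dtype=float)
    if dlist.size == 0:
        return 0.0
    if np.any(dlist.indices >= len(theta)):
        raise ValueError("theta does not cover all listed units")
    return float(np.mean(theta[dlist.indices] == 0.0))


def wasserstein1(d1, d2) -> float:
    """1-Wasserstein distance between two discrete distributions, each given
    as ``(support, weights)``.  Total masses must agree (within 1e-8)."""
    v1, w1 = (np.asarray(a, dtype=float) for a in d1)
    v2, w2 = (np.asarray(a, dtype=float) for a in d2)
    if v1.shape != w1.shape or v2.shape != w2.shape:
        raise ValueError("each distribution must be (support, weights) of equal shape")
    if abs(w1.sum() - w2.sum()) > 1e-8:
        raise ValueError(
            f"total masses differ: {w1.sum():.12g} vs {w2.sum():.12g}"
        )
    return float(
        _stats.wasserstein_distance(v1, v2, u_weights=w1, v_weights=w2)
    )


def true_effect_distribution(
    spec: ScenarioSpec, pi0: float, n_grid: int = 2001
) -> tuple:
    """Discretize the true effect mixture pi0*delta_0 + (1-pi0)*g_alt onto a
    fine regular grid (cell masses from the mixture CDF), for scoring the
    estimated mixing distribution by Wasserstein distance."""
    w = np.array([c[0] for c in spec.alt_components])
    centers = np.array([c[1] for c in spec.alt_components])
    sds = np.array([c[2] for c in spec.alt_components])
    half = float(np.max(np.abs(centers) + 4.0 * sds))
    edges = np.linspace(-half, half, n_grid + 1)
    cdf = np.zeros_like(edges)
    for wj, cj, sj in zip(w, centers, sds):
        cdf += wj * _stats.norm.cdf(edges, loc=cj, scale=sj)
    mass = (1.0 - pi0) * np.diff(cdf)
    support = 0.5 * (edges[:-1] + edges[1:])
    # unabsorbed tail mass of g_alt beyond +-4 sd goes to the end cells
    tail_lo = (1.0 - pi0) * cdf[0]
    tail_hi = (1.0 - pi0) * (1.0 - cdf[-1])
    mass[0] += tail_lo
    mass[-1] += tail_hi
    support = np.concatenate([support, [0.0]])
    mass = np.concatenate([mass, [pi0]])
    return support, mass


def run_operating_characteristics(
    specs: Sequence[ScenarioSpec],
    reps: int,
    nominal_levels: Sequence[float] = (0.05, 0.10),
    seed: int = 0,
    K: int = 15,
    L: int = 10,
) -> pd.DataFrame:
    """Replicate-level operating characteristics across scenarios.

    Per replicate: draw pi0 (Uniform[0.5, 1] unless the spec fixes it),
    simulate, fit, and record the pi0 estimate, the 1-Wasserstein error of
    the estimated effect distribution against the truth, and the
    false-discovery proportion / list size of the lfdr-thresholded list at
    each nominal level.  Returns a long-format table, one row per
    (scenario, replicate, level); fit failures are recorded with
    ``failed=True`` and NaN metrics.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for spec in specs:
        spec_ss = root.spawn(1)[0]
        child_seeds = spec_ss.generate_state(2 * reps) % (2**31)
        for rep in range(reps):
            pi0_rng = np.random.default_rng(int(child_seeds[2 * rep]))
            pi0 = spec.pi0 if spec.pi0 is not None else float(
                pi0_rng.uniform(0.5, 1.0)
            )
            data_seed = int(child_seeds[2 * rep + 1])
            try:
                study = simulate_dataset(spec, seed=data_seed, pi0=pi0)
                fit = fit_mixtwice(study.stats, K=K, L=L)
                post = posterior_effects(fit, study.stats)
                pi0_hat = estimate_pi0(fit)
                w1 = wasserstein1(
                    (fit.egrid.values, fit.g),
                    true_effect_distribution(spec, pi0),
                )
                failed = False
            except Exception:
                fit = post = None
                pi0_hat = w1 = float("nan")
                failed = True
            for level in nominal_levels:
                if failed:
                    fdp = n_disc = float("nan")
                else:
                    dl = discovery_list(post, level, "lfdr")
                    fdp = empirical_fdp(dl, study.theta)
                    n_disc = dl.size
                rows.append(
                    {
                        "scenario": spec.name,
                        "rep": rep,
                        "seed": data_seed,
                        "pi0": pi0,
                        "pi0_hat": pi0_hat,
                        "w1_error": w1,
                        "level": float(level),
                        "fdp": fdp,
                        "n_discoveries": n_disc,
                        "failed": failed,
                    }
                )
    return pd.DataFrame(rows)


def _stratum_label(pi0: float) -> str:
    for lo, hi in PI0_STRATA:
        if lo <= pi0 <= hi:
            return f"[{lo}, {hi}]"
    return "outside"


def aggregate_by_pi0_strata(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate results within the four pi0 strata: empirical FDR
    (mean FDP), mean pi0 estimate, mean Wasserstein error; failed replicates
    are excluded and counted."""
    df = results.copy()
    df["stratum"] = df["pi0"].map(_stratum_label)
    ok = df[~df["failed"]]
    agg = (
        ok.groupby(["scenario", "stratum", "level"], as_index=False)
        .agg(
            empirical_fdr=("fdp", "mean"),
            mean_pi0=("pi0", "mean"),
            mean_pi0_hat=("pi0_hat", "mean"),
            mean_w1_error=("w1_error", "mean"),
            mean_list_size=("n_discoveries", "mean"),
            n_reps=("fdp", "size"),
        )
    )
    n_failed = (
        df.groupby(["scenario", "stratum", "level"], as_index=False)["failed"]
        .sum()
        .rename(columns={"failed": "n_failed"})
    )
    return agg.merge(n_failed, on=["scenario", "stratum", "level"], how="left")
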