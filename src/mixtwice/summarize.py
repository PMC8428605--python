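"""Two-group frontend: intensity transform, per-unit summaries, permutation null.

Raw array intensities are variance-stabilized with a double natural log,
then each unit is reduced to an estimated effect (difference of group means,
case minus reference), its squared standard error from the pooled variance,
and the design degrees of freedom ``n1 + n2 - 2`` shared across units.  The
permutation-null procedure refits the model after shuffling the sample
labels, a negative control for the discovery lists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fit import fit_mixtwice
from .inference import discovery_list, posterior_effects
from .model_core import DegenerateDataError, SummaryStats

__all__ = [
    "GroupedMatrix",
    "PermutationNullResult",
    "double_log",
    "two_group_summary",
    "permutation_null",
]


@dataclass(frozen=True)
class GroupedMatrix:
    """Units x samples intensity table with a two-group sample labelling.

    ``reference`` names the baseline group; effects are reported as
    (other group) minus (reference).  If omitted, the first label in
    column order is the reference.
    """

    values: np.ndarray  # (m, n_samples), post-transform scale
    labels: np.ndarray  # (n_samples,) exactly two distinct values
    unit_ids: Optional[np.ndarray] = None
    reference: Optional[str] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D units x samples array")
        labels = np.asarray(self.labels, dtype=object).reshape(-1)
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"labels length {len(labels)} does not match "
                f"{values.shape[1]} sample columns"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("intensity values must be finite")
        distinct = list(dict.fromkeys(labels))
        if len(distinct) != 2:
            raise ValueError(f"exactly two groups required, got {distinct}")
        ref = self.reference if self.reference is not None else distinct[0]
        if ref not in distinct:
            raise ValueError(f"reference group {ref!r} not among labels {distinct}")
        case = distinct[0] if distinct[1] == ref else distinct[1]
        n1 = int(np.sum(labels == ref))
        n2 = int(np.sum(labels == case))
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs at least 2 samples")
        ids = self.unit_ids
        if ids is None:
            ids = np.array([f"unit{i}" for i in range(values.shape[0])], dtype=object)
        else:
            ids = np.asarray(ids, dtype=object).reshape(-1)
            if len(ids) != values.shape[0]:
                raise ValueError("unit_ids length must match number of rows")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "unit_ids", ids)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "_case", case)
        object.__setattr__(self, "n1", n1)
        object.__setattr__(self, "n2", n2)

    @property
    def case(self) -> str:
        return self._case

    @property
    def m(self) -> int:
        return self.values.shape[0]


def double_log(y):
    """Double natural log ``log(log(y))``, a variance-stabilizing transform
    for fluorescence intensities.  Requires ``y > 1``."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 1.0):
        raise ValueError("double_log requires y > 1 (log log undefined otherwise)")
    return np.log(np.log(y))


def two_group_summary(
    gm: GroupedMatrix, variance_floor: Optional[float] = None
) -> SummaryStats:
    """Per-unit effect, squared standard error and shared df.

    x_i    = mean(case) - mean(reference)
    v_i    = [(n1-1) var1 + (n2-1) var2] / (n1 + n2 - 2)   (pooled, ddof=1)
    s2_i   = v_i * (1/n1 + 1/n2)
    df     = n1 + n2 - 2

    Units with zero pooled variance raise (named), unless an explicit
    ``variance_floor`` is supplied to clip them.
    """
    mask_ref = gm.labels == gm.reference
    mask_case = ~mask_ref
    y1 = gm.values[:, mask_ref]
    y2 = gm.values[:, mask_case]
    n1, n2 = gm.n1, gm.n2
    x = y2.mean(axis=1) - y1.mean(axis=1)
    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if variance_floor is not None:
        pooled = np.maximum(pooled, float(variance_floor))
    zero = pooled <= 0
    if np.any(zero):
        ids = ", ".join(map(str, gm.unit_ids[zero][:10]))
        raise DegenerateDataError(
            f"zero pooled variance for unit(s): {ids}; "
            "pass variance_floor to clip (off by default)"
        )
    s2 = pooled * (1.0 / n1 + 1.0 / n2)
    return SummaryStats(unit_ids=gm.unit_ids, x=x, s2=s2, df=float(n1 + n2 - 2))


@dataclass(frozen=True)
class PermutationNullResult:
    """Discovery-list sizes across label permutations, with a tabulation."""

    sizes: np.ndarray
    tabulation: dict  # size -> count
    alpha: float

    @property
    def n_perm(self) -> int:
        return len(self.sizes)

    @property
    def fraction_empty(self) -> float:
        return float(np.mean(self.sizes == 0)) if len(self.sizes) else float("nan")


def permutation_null(
    gm: GroupedMatrix,
    n_perm: int,
    alpha: float = 0.10,
    K: int = 15,
    L: int = 10,
    seed: int = 0,
    mode: float = 0.0,
) -> PermutationNullResult:
    """Negative control: shuffle sample labels, refit, count discoveries.

    Each permutation preserves the multiset of labels (hence group sizes),
    recomputes the two-group summaries, refits the mixture and thresholds
    the lfdr at ``alpha``.  Fully determined by ``seed``.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        perm_labels = rng.permutation(gm.labels)
        gm_p = GroupedMatrix(
            values=gm.values,
            labels=perm_labels,
            unit_ids=gm.unit_ids,
            reference=gm.reference,
        )
        stats = two_group_summary(gm_p)
        fit = fit_mixtwice(stats, K=K, L=L, mode=mode)
        post = posterior_effects(fit, stats)
        sizes[p] = discovery_list(post, alpha, "lfdr").size
    return PermutationNullResult(
        sizes=sizes, tabulation=dict(sorted(Counter(sizes.tolist()).items())), alpha=alpha
    )
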