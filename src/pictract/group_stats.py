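"""Two-level inference on connectivity matrices.

Level one, per participant: the pooled seed-by-target maximum-connectivity
values are modelled as Poisson; the fitted rate lambda sets an individual
threshold at p = .05, and a connection is retained when its value is
*strictly greater* than that threshold.  Level two, across participants:
a connection enters the group profile when it survives level one in over
75% of participants (strict criterion; at least 10 of 13) or over 50%
(relaxed; at least 7 of 13).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix

__all__ = [
    "PoissonModel",
    "GroupProfile",
    "fit_poisson_lambda",
    "poisson_threshold",
    "apply_individual_threshold",
    "group_consistency",
    "consistency_count",
]


def fit_poisson_lambda(values) -> float:
    """Maximum-likelihood Poisson rate of pooled connectivity values.

    The MLE is the sample mean.  Zeros are part of the pooled distribution
    (most seed-target pairs are unconnected) and are included by default;
    exclude them upstream for sensitivity analyses.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("cannot fit a Poisson rate to no values")
    if np.any(values < 0):
        raise ValueError("connectivity values must be non-negative")
    return float(values.mean())


def poisson_threshold(lam: float, alpha: float = 0.05) -> int:
    """Smallest integer t with P(X > t | lambda) < alpha, X ~ Poisson.

    Connections with value strictly above t are deemed present.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if lam == 0:
        return 0
    # start below the answer, then walk up; sf(t) = P(X > t)
    t = max(0, int(stats.poisson.ppf(1.0 - alpha, lam)) - 2)
    while stats.poisson.sf(t, lam) >= alpha:
        t += 1
    return t


@dataclass
class PoissonModel:
    """Fitted per-participant null model and its p = .05 cut-off."""

    lam: float
    alpha: float = 0.05
    threshold: int = field(init=False)

    def __post_init__(self):
        self.threshold = poisson_threshold(self.lam, self.alpha)

    @classmethod
    def fit(cls, values, alpha: float = 0.05) -> "PoissonModel":
        return cls(lam=fit_poisson_lambda(values), alpha=alpha)


def apply_individual_threshold(
    matrix: ConnectivityMatrix, model: PoissonModel
) -> np.ndarray:
    """Boolean matrix of connections exceeding the individual threshold."""
    return np.asarray(matrix.values) > model.threshold


def consistency_count(frac: float, n_participants: int) -> int:
    """Minimum participant count satisfying 'over ``frac``' of N.

    Strictly more than frac*N, integer-exact: floor(frac*N) + 1.  For
    N = 13 this gives 10 at 75% and 7 at 50%.
    """
    return int(np.floor(frac * n_participants)) + 1


@dataclass
class GroupProfile:
    """Per-connection participant counts with consistency flags."""

    seed_labels: list[str]
    target_labels: list[str]
    counts: np.ndarray  # (n_seeds, n_targets) int
    strict_pass: np.ndarray  # bool
    relaxed_pass: np.ndarray  # bool
    n_participants: int
    strict_min: int
    relaxed_min: int

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, s in enumerate(self.seed_labels):
            for j, t in enumerate(self.target_labels):
                rows.append(
                    {
                        "seed": s,
                        "target": t,
                        "participant_count": int(self.counts[i, j]),
                        "strict_pass": bool(self.strict_pass[i, j]),
                        "relaxed_pass": bool(self.relaxed_pass[i, j]),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["seed", "target", "participant_count", "strict_pass",
                     "relaxed_pass"],
        )


def group_consistency(
    binary_matrices: list[np.ndarray],
    seed_labels: list[str],
    target_labels: list[str],
    strict_frac: float = 0.75,
    relaxed_frac: float = 0.50,
) -> GroupProfile:
    """Count participants per connection and apply both consistency rules."""
    if not binary_matrices:
        raise ValueError("need at least one participant")
    shape = np.asarray(binary_matrices[0]).shape
    for m in binary_matrices:
        if np.asarray(m).shape != shape:
            raise ValueError("participant matrices differ in shape")
    n = len(binary_matrices)
    counts = np.sum([np.asarray(m, dtype=int) for m in binary_matrices], axis=0)
    strict_min = consistency_count(strict_frac, n)
    relaxed_min = consistency_count(relaxed_frac, n)
    return GroupProfile(
        seed_labels=list(seed_labels),
        target_labels=list(target_labels),
        counts=counts,
        strict_pass=counts >= strict_min,
        relaxed_pass=counts >= relaxed_min,
        n_participants=n,
        strict_min=strict_min,
        relaxed_min=relaxed_min,
    )
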