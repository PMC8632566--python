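"""Hybrid class rebalancing for training folds.

The scheme: when the minority class makes up less than a target fraction
(default one third) of the training fold, SMOTE-oversample it up to
exactly that fraction, then randomly undersample the majority class to
parity; when the imbalance is milder than the target, undersample only.
Test data are never touched, so the test class distribution stays
representative of the collected data.

SMOTE synthesises a minority sample as ``x + u * (x_nn - x)`` with
``u ~ Uniform(0, 1)``, ``x`` a randomly drawn minority row and ``x_nn``
one of its k nearest minority neighbours (Euclidean).  In the pipeline
this runs on already-standardised features, so the metric is sensible.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ResampleConfig:
    #: target minority share after oversampling ("33%" read as exactly 1/3)
    minority_target_fraction: float = 1.0 / 3.0
    smote_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.minority_target_fraction <= 0.5:
            raise ValueError("minority_target_fraction must be in (0, 0.5]")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


@dataclasses.dataclass(frozen=True)
class ResamplePlan:
    n_minority: int
    n_majority: int
    n_synthetic_minority: int
    n_majority_keep: int
    branch: str  # smote_then_undersample | undersample_only | none


class DegenerateClassError(ValueError):
    """Raised when a training fold lacks the rows needed to rebalance."""


def plan_resampling(
    n_minority: int, n_majority: int, config: ResampleConfig | None = None
) -> ResamplePlan:
    """Decide the rebalancing branch and counts for one training fold.

    With minority share below the target fraction f, the minority is grown
    to the smallest m' with m' / (m' + n_majority) >= f (integer ceiling of
    f * n_majority / (1 - f)) and the majority undersampled to m'.  With
    milder skew the majority is undersampled straight to the minority
    count.  A minority of one row cannot be interpolated, so such folds
    fall back to undersampling only (logged).
    """
    config = config or ResampleConfig()
    config.validate()
    if n_minority == 0:
        raise DegenerateClassError("training fold has a single class (minority n=0)")
    if n_minority > n_majority:
        raise ValueError("n_minority must be <= n_majority")
    if n_minority == n_majority:
        return ResamplePlan(n_minority, n_majority, 0, n_majority, "none")

    f = config.minority_target_fraction
    if n_minority / (n_minority + n_majority) < f:
        # smallest integer m' with m' / (m' + n_majority) >= f; the float
        # ceiling is adjusted to guard against representation error
        target = math.ceil(f * n_majority / (1.0 - f) - 1e-9)
        while target / (target + n_majority) < f:
            target += 1
        while target > 1 and (target - 1) / (target - 1 + n_majority) >= f:
            target -= 1
        if n_minority < 2:
            logger.warning(
                "minority class has %d row(s); SMOTE impossible, "
                "falling back to undersampling only",
                n_minority,
            )
            return ResamplePlan(n_minority, n_majority, 0, n_minority, "undersample_only")
        return ResamplePlan(
            n_minority,
            n_majority,
            target - n_minority,
            target,
            "smote_then_undersample",
        )
    return ResamplePlan(n_minority, n_majority, 0, n_minority, "undersample_only")


def smote_oversample(
    minority_rows: np.ndarray, n_new: int, k: int, seed: int
) -> np.ndarray:
    """Synthesise ``n_new`` minority rows by k-NN convex interpolation."""
    minority_rows = np.asarray(minority_rows, dtype=float)
    if n_new == 0:
        return np.empty((0, minority_rows.shape[1]))
    if len(minority_rows) < 2:
        raise DegenerateClassError("SMOTE needs at least 2 minority rows")
    k = min(k, len(minority_rows) - 1)
    rng = np.random.default_rng(seed)
    # +1 because each row is its own nearest neighbour
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_rows)
    _, neighbours = nn.kneighbors(minority_rows)
    base = rng.integers(0, len(minority_rows), n_new)
    pick = rng.integers(1, k + 1, n_new)
    targets = neighbours[base, pick]
    u = rng.random((n_new, 1))
    x = minority_rows[base]
    return x + u * (minority_rows[targets] - x)


def apply_plan(
    rows: np.ndarray,
    labels: np.ndarray,
    plan: ResamplePlan,
    config: ResampleConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance one training fold according to ``plan``.

    All original minority rows are retained; the undersampled majority is
    a uniform random subset; synthetic rows (if any) are appended after
    the retained originals.
    """
    config = config or ResampleConfig()
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    minority = min(counts, key=counts.get) if counts[0] != counts[1] else None
    if plan.branch == "none":
        if counts[0] != counts[1]:
            raise ValueError("plan says 'none' but fold classes are unequal")
        return rows, labels
    if minority is None:
        raise ValueError(f"plan says {plan.branch!r} but fold classes are equal")
    majority = 1 - minority
    if counts[minority] != plan.n_minority or counts[majority] != plan.n_majority:
        raise ValueError(
            f"plan built for counts ({plan.n_minority}, {plan.n_majority}) "
            f"but fold has ({counts[minority]}, {counts[majority]})"
        )

    rng = np.random.default_rng(config.seed)
    min_rows = rows[labels == minority]
    maj_rows = rows[labels == majority]
    keep = rng.choice(len(maj_rows), size=plan.n_majority_keep, replace=False)
    maj_kept = maj_rows[keep]

    if plan.branch == "smote_then_undersample":
        synthetic = smote_oversample(
            min_rows,
            plan.n_synthetic_minority,
            config.smote_k,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        min_all = np.vstack([min_rows, synthetic])
    else:
        min_all = min_rows

    out_rows = np.vstack([min_all, maj_kept])
    out_labels = np.concatenate(
        [np.full(len(min_all), minority), np.full(len(maj_kept), majority)]
    )
    return out_rows, out_labels
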