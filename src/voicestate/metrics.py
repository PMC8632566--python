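"""Binary classifier performance measures.

Besides the standard proportions (accuracy, sensitivity = TP/P,
specificity = TN/N) this module implements

* the F1 score in the form TP / (TP + (FP + FN)/2), algebraically equal
  to the harmonic mean of precision and recall;
* ROC/AUC via the Mann–Whitney pairwise probability (ties count 1/2),
  delegated to scikit-learn;
* B10, a log-scale Bayes factor testing statistical dependence between
  predicted and true labels in the 2x2 confusion table, built with
  intrinsic priors.

B10 background.  Under multinomial sampling of the four cells, the null
model M0 of independence has cell probabilities p_ij = a_i * b_j with
uniform (Beta(1,1)) priors on the row and column probabilities a, b; the
alternative M1 is the unrestricted multinomial with a Dirichlet(1,1,1,1)
prior turned into an intrinsic prior conditional on M0.  With a training
sample of size t the intrinsic construction collapses to a finite
mixture: the marginal of the observed table x under M1 becomes

    m1(x) = sum_z  m0(z) * DirMult(x | 1 + z)

where z ranges over 2x2 tables with total t, m0(z) is the null prior
predictive of z, and DirMult(x | 1 + z) the Dirichlet-multinomial
posterior predictive of x given pseudo-counts z.  B10 = ln m1(x)/m0(x).
We take t equal to the observed sample size; the sum is evaluated
exactly when the number of training tables is modest and otherwise by a
seeded Monte-Carlo draw of z from the null predictive.  Interpretation
bands: below 0 evidence against dependence, 1-3 positive, 3-5 strong,
above 5 decisive evidence of dependence.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
from scipy.special import betaln, gammaln, logsumexp
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: rows = predicted (pos/neg), columns = true (pos/neg)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclasses.dataclass
class MetricSet:
    """One fold's performance; metrics undefined for the fold are None."""

    accuracy: float | None = None
    f1: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    b10: float | None = None

    FIELDS = ("accuracy", "f1", "sensitivity", "specificity", "auc", "b10")


def confusion(y_true, y_pred) -> ConfusionTable:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors differ in length")
    return ConfusionTable(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def accuracy(ct: ConfusionTable) -> float:
    if ct.total == 0:
        raise ValueError("empty confusion table")
    return (ct.tp + ct.tn) / ct.total


def f1(ct: ConfusionTable) -> float | None:
    """TP / (TP + mean(FP, FN)); None when no positives appear anywhere."""
    denom = ct.tp + (ct.fp + ct.fn) / 2.0
    if denom == 0:
        logger.warning("F1 undefined: no true or predicted positives")
        return None
    return ct.tp / denom


def sensitivity(ct: ConfusionTable) -> float | None:
    pos = ct.tp + ct.fn
    if pos == 0:
        return None
    return ct.tp / pos


def specificity(ct: ConfusionTable) -> float | None:
    neg = ct.tn + ct.fp
    if neg == 0:
        return None
    return ct.tn / neg


def roc_auc(scores, y_true) -> float | None:
    """Mann–Whitney AUC: P(score+ > score-) + P(tie)/2; None if single-class."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        return None
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def roc_curve(scores, y_true) -> np.ndarray:
    """Ordered ROC points as an (n, 3) array of (fpr, tpr, threshold)."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC curve needs both classes")
    fpr, tpr, thr = _sk_roc_curve(y_true, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    return np.column_stack([fpr, tpr, thr])


# ---------------------------------------------------------------------------
# B10: intrinsic-prior Bayes factor for dependence in the 2x2 table
# ---------------------------------------------------------------------------


def _log_multinomial_coef(counts: np.ndarray, axis=None) -> np.ndarray:
    n = counts.sum(axis=axis)
    return gammaln(n + 1) - gammaln(counts + 1).sum(axis=axis)


def _log_m0(x: np.ndarray) -> float:
    """Null (independence) marginal of a 2x2 table under Beta(1,1) priors."""
    tp, fp, fn, tn = x
    lc = float(_log_multinomial_coef(x))
    return lc + betaln(tp + fp + 1, fn + tn + 1) + betaln(tp + fn + 1, fp + tn + 1)


def _log_terms(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """log [ m0(z) * DirMult(x | 1 + z) ] for an array of training tables z."""
    t = int(z[0].sum())
    n = int(x.sum())
    lc_z = _log_multinomial_coef(z, axis=1)
    log_m0_z = (
        lc_z
        + betaln(z[:, 0] + z[:, 1] + 1, z[:, 2] + z[:, 3] + 1)
        + betaln(z[:, 0] + z[:, 2] + 1, z[:, 1] + z[:, 3] + 1)
    )
    log_dm = (
        float(_log_multinomial_coef(x))
        + gammaln(t + 4)
        - gammaln(n + t + 4)
        + (gammaln(x[None, :] + z + 1) - gammaln(z + 1)).sum(axis=1)
    )
    return log_m0_z + log_dm


def _enumerate_tables(t: int) -> np.ndarray:
    """All 2x2 tables with total t, shape (C(t+3,3), 4)."""
    blocks = []
    for z1 in range(t + 1):
        r = t - z1
        z2, z3 = np.meshgrid(np.arange(r + 1), np.arange(r + 1), indexing="ij")
        mask = z2 + z3 <= r
        z2, z3 = z2[mask], z3[mask]
        z4 = r - z2 - z3
        blocks.append(
            np.column_stack([np.full(len(z2), z1), z2, z3, z4])
        )
    return np.concatenate(blocks)


def _log_m1_exact(x: np.ndarray, t: int) -> float:
    parts = []
    for z1 in range(t + 1):
        r = t - z1
        z2, z3 = np.meshgrid(np.arange(r + 1), np.arange(r + 1), indexing="ij")
        mask = z2 + z3 <= r
        z2, z3 = z2[mask], z3[mask]
        z = np.column_stack([np.full(len(z2), z1), z2, z3, r - z2 - z3])
        parts.append(logsumexp(_log_terms(x, z)))
    return float(logsumexp(parts))


def _log_m1_mc(x: np.ndarray, t: int, n_mc: int, seed: int) -> float:
    """Monte-Carlo estimate: z ~ null prior predictive, average DirMult(x|1+z)."""
    rng = np.random.default_rng(seed)
    a = rng.beta(1.0, 1.0, n_mc)
    b = rng.beta(1.0, 1.0, n_mc)
    p = np.column_stack([a * b, a * (1 - b), (1 - a) * b, (1 - a) * (1 - b)])
    z = rng.multinomial(t, p)
    n = int(x.sum())
    log_dm = (
        float(_log_multinomial_coef(x))
        + gammaln(t + 4)
        - gammaln(n + t + 4)
        + (gammaln(x[None, :] + z + 1) - gammaln(z + 1)).sum(axis=1)
    )
    return float(logsumexp(log_dm) - np.log(n_mc))


#: largest number of enumerated training tables before the seeded
#: Monte-Carlo path takes over (t <= ~180)
_EXACT_TABLE_LIMIT = 1_000_000


def b10(
    ct: ConfusionTable,
    training_size: int | None = None,
    n_mc: int = 20_000,
    seed: int = 0,
) -> float | None:
    """Natural-log Bayes factor for dependence between predicted and true
    labels; None (with a warning) on tables with an all-zero margin.

    ``training_size`` is the intrinsic-prior training sample size t
    (default: the observed total).
    """
    x = np.array([ct.tp, ct.fp, ct.fn, ct.tn], dtype=int)
    n = int(x.sum())
    if n == 0:
        raise ValueError("empty confusion table")
    margins = (ct.tp + ct.fp, ct.fn + ct.tn, ct.tp + ct.fn, ct.fp + ct.tn)
    if 0 in margins:
        logger.warning("B10 undefined: confusion table has an all-zero margin")
        return None
    t = int(training_size) if training_size is not None else n
    n_tables = (t + 1) * (t + 2) * (t + 3) // 6
    if n_tables <= _EXACT_TABLE_LIMIT:
        log_m1 = _log_m1_exact(x, t)
    else:
        log_m1 = _log_m1_mc(x, t, n_mc, seed)
    return log_m1 - _log_m0(x)


# ---------------------------------------------------------------------------


def metric_set(
    y_true,
    y_pred,
    scores=None,
    with_b10: bool = True,
    b10_seed: int = 0,
) -> MetricSet:
    """All fold metrics from labels (and scores, for AUC) in one call."""
    ct = confusion(y_true, y_pred)
    return MetricSet(
        accuracy=accuracy(ct),
        f1=f1(ct),
        sensitivity=sensitivity(ct),
        specificity=specificity(ct),
        auc=roc_auc(scores, y_true) if scores is not None else None,
        b10=b10(ct, seed=b10_seed) if with_b10 else None,
    )


@dataclasses.dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float
    n: int
    n_missing: int


def summarize_folds(metric_sets: Iterable[MetricSet]) -> dict[str, SummaryStat]:
    """Per-metric mean and sample SD over folds, skipping undefined folds.

    Sample (n-1) SD; a single defined fold reports SD 0.0.  The count of
    folds where the metric was undefined is carried along.
    """
    metric_sets = list(metric_sets)
    if not metric_sets:
        raise ValueError("no folds to summarize")
    out: dict[str, SummaryStat] = {}
    for name in MetricSet.FIELDS:
        values = [getattr(m, name) for m in metric_sets]
        defined = [v for v in values if v is not None]
        n_missing = len(values) - len(defined)
        if n_missing:
            logger.info("%s undefined in %d of %d folds", name, n_missing, len(values))
        if not defined:
            out[name] = SummaryStat(float("nan"), float("nan"), 0, n_missing)
            continue
        mean = float(np.mean(defined))
        sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        out[name] = SummaryStat(mean, sd, len(defined), n_missing)
    return out
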