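"""Iterative pruning of base classifiers with highly correlated predictions.

Rationale: a base classifier earns its place in a stacked ensemble by being
usefully different from the others.  The scheme computes the Pearson
correlation matrix of the learners' out-of-fold probability vectors, finds
the most correlated pair, and — while that maximum exceeds the threshold
(default 0.75) — removes the pair member whose average correlation to the
*remaining* learners is higher, then recomputes on the shrunken matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric unit-diagonal Pearson correlations between learners."""

    learner_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "learner_names", tuple(self.learner_names))
        l = len(self.learner_names)
        if v.shape != (l, l):
            raise ValueError(f"matrix shape {v.shape} does not match {l} names")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(v)) > 1.0 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def l(self) -> int:
        return len(self.learner_names)

    def drop(self, name: str) -> "CorrelationMatrix":
        keep = [i for i, n in enumerate(self.learner_names) if n != name]
        return CorrelationMatrix(
            learner_names=tuple(self.learner_names[i] for i in keep),
            values=self.values[np.ix_(keep, keep)],
        )


@dataclass(frozen=True)
class RemovalConfig:
    """Correlation cutoff above which a pair triggers a removal."""

    threshold: float = 0.75

    def __post_init__(self) -> None:
        if self.threshold <= 0.0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if self.threshold >= 1.0:
            logger.info(
                "threshold %.3f >= 1: no pair can exceed it, pruning disabled",
                self.threshold,
            )


@dataclass(frozen=True)
class IterationRecord:
    max_pair: tuple[str, str]
    max_corr: float
    avg_a: float
    avg_b: float
    removed: str
    tie_break: str | None = None


@dataclass
class RemovalTrace:
    """Ordered log of pruning decisions plus the surviving learner names."""

    iterations: list[IterationRecord] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "iterations": [
                    {
                        "max_pair": list(r.max_pair),
                        "max_corr": r.max_corr,
                        "avg_a": r.avg_a,
                        "avg_b": r.avg_b,
                        "removed": r.removed,
                        "tie_break": r.tie_break,
                    }
                    for r in self.iterations
                ],
                "survivors": self.survivors,
            },
            indent=2,
        )


def prediction_correlation_matrix(
    oof_matrix: np.ndarray, learner_names: Sequence[str]
) -> CorrelationMatrix:
    """Pearson correlation of each pair of OOF probability columns.

    Requires complete columns (invalid learners must already be ejected)
    and non-constant columns; symmetry is enforced exactly.
    """
    oof = np.asarray(oof_matrix, dtype=float)
    if oof.ndim != 2 or oof.shape[1] != len(learner_names):
        raise ValueError("oof_matrix must be n x l with one column per learner")
    if oof.shape[1] < 2:
        raise ValueError("need at least two learners for a correlation matrix")
    if np.isnan(oof).any():
        bad = [learner_names[j] for j in np.unique(np.argwhere(np.isnan(oof))[:, 1])]
        raise ValueError(f"missing OOF predictions for learners: {bad}")
    stds = oof.std(axis=0)
    if (stds == 0).any():
        bad = [learner_names[j] for j in np.flatnonzero(stds == 0)]
        raise ValueError(f"constant prediction column for learners: {bad}")
    corr = np.corrcoef(oof, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(learner_names=tuple(learner_names), values=corr)


def find_max_pair(corr: CorrelationMatrix) -> tuple[tuple[str, str], float]:
    """Maximum entry of the upper-triangular correlation matrix.

    Ties are broken by lexicographic order of the name pair (logged).
    """
    if corr.l < 2:
        raise ValueError("need at least two learners")
    iu, ju = np.triu_indices(corr.l, k=1)
    vals = corr.values[iu, ju]
    vmax = vals.max()
    tied = np.flatnonzero(vals >= vmax - 1e-12)
    pairs = sorted(
        tuple(sorted((corr.learner_names[iu[t]], corr.learner_names[ju[t]])))
        for t in tied
    )
    if len(tied) > 1:
        logger.info("max-correlation tie among %d pairs; taking %s", len(tied), pairs[0])
    return pairs[0], float(vmax)


def _avg_corr_to_others(corr: CorrelationMatrix, name: str) -> float:
    """Mean correlation of *name* to every other remaining learner."""
    i = corr.learner_names.index(name)
    others = [j for j in range(corr.l) if j != i]
    return float(corr.values[i, others].mean())


def removal_iteration(
    corr: CorrelationMatrix,
    cfg: RemovalConfig,
    cv_aucs: Mapping[str, float],
) -> tuple[str | None, IterationRecord | None]:
    """One pruning step.

    If the maximum pair correlation exceeds the threshold, the pair member
    with the larger mean correlation to all other remaining learners is
    removed; an exact tie removes the member with the lower CV AUC.
    Returns ``(None, None)`` when nothing exceeds the threshold.
    """
    (a, b), vmax = find_max_pair(corr)
    if vmax <= cfg.threshold:
        return None, None
    avg_a = _avg_corr_to_others(corr, a)
    avg_b = _avg_corr_to_others(corr, b)
    tie_break = None
    if avg_a > avg_b:
        removed = a
    elif avg_b > avg_a:
        removed = b
    else:
        removed = a if cv_aucs.get(a, 0.0) <= cv_aucs.get(b, 0.0) else b
        tie_break = "equal average correlation; removed lower CV AUC"
        logger.info("average-correlation tie between %s and %s: %s", a, b, tie_break)
    record = IterationRecord(
        max_pair=(a, b),
        max_corr=vmax,
        avg_a=avg_a,
        avg_b=avg_b,
        removed=removed,
        tie_break=tie_break,
    )
    return removed, record


def run_removal_matrix(
    corr: CorrelationMatrix,
    cfg: RemovalConfig,
    cv_aucs: Mapping[str, float],
) -> RemovalTrace:
    """Iterate pruning on a precomputed correlation matrix until the maximum
    remaining pair correlation is at or below the threshold (or one learner
    remains)."""
    trace = RemovalTrace()
    current = corr
    while current.l >= 2:
        removed, record = removal_iteration(current, cfg, cv_aucs)
        if removed is None:
            break
        trace.iterations.append(record)
        current = current.drop(removed)
    trace.survivors = list(current.learner_names)
    return trace


def run_removal(
    oof_matrix: np.ndarray,
    learner_names: Sequence[str],
    cfg: RemovalConfig,
    cv_aucs: Mapping[str, float],
) -> RemovalTrace:
    """Full scheme from OOF predictions: correlation matrix then iterative
    pruning.  A single learner survives trivially."""
    names = list(learner_names)
    if len(names) == 1:
        return RemovalTrace(iterations=[], survivors=names)
    corr = prediction_correlation_matrix(oof_matrix, names)
    return run_removal_matrix(corr, cfg, cv_aucs)
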