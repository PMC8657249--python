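"""Ensemble feature importance: weighted rank aggregation + knee truncation.

Each surviving base learner contributes a within-learner importance ranking
(rank 1 = most important; ties get average ranks).  Rankings are combined as
a weighted sum, each learner weighted by its share of the meta-classifier's
absolute coefficient mass, so features consistently top-ranked by the
influential learners get the lowest aggregated score.  The count of
"important" features is the knee of the ascending score sequence, found by
fitting two least-squares lines and minimizing the total residual sum of
squares.  Direction signs come from the tuned logistic-regression base
learner's coefficients; multi-level categorical features stay unsigned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from stackprune.cohort import FeatureEncoder, FeatureSchema
from stackprune.learners import HingeFeatures, TunedLearner

logger = logging.getLogger(__name__)


@dataclass
class ImportanceTable:
    """Aggregated importance ranking with per-learner detail.

    ``feature_names`` is ordered best-first; ``aggregated_score`` is the
    weighted rank sum (lower = more important); ``knee_index`` is the count
    of features flagged important; ``direction`` maps each feature to
    ``positive`` / ``negative`` / ``categorical`` / ``unsigned``.
    """

    feature_names: list[str]
    per_learner_ranks: pd.DataFrame
    meta_weight_share: dict[str, float]
    aggregated_score: pd.Series
    knee_index: int
    direction: dict[str, str]
    no_clear_knee: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "score": [self.aggregated_score[f] for f in self.feature_names],
                "rank": np.arange(1, len(self.feature_names) + 1),
                "direction": [self.direction[f] for f in self.feature_names],
                "important": [
                    i < self.knee_index for i in range(len(self.feature_names))
                ],
            }
        )

    def plot(self, ax=None):
        """Horizontal importance bars, colored by direction (blue positive,
        red negative, grey categorical/unsigned); best feature on top."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * len(self.feature_names) + 1))
        colors = {
            "positive": "tab:blue",
            "negative": "tab:red",
            "categorical": "grey",
            "unsigned": "grey",
        }
        names = self.feature_names[::-1]
        p = len(names)
        # invert scores so longer bars mean more important
        scores = np.array([self.aggregated_score[f] for f in names])
        heights = scores.max() + 1 - scores
        ax.barh(
            np.arange(p),
            heights,
            color=[colors[self.direction[f]] for f in names],
        )
        ax.set_yticks(np.arange(p))
        ax.set_yticklabels(names)
        ax.axhline(p - self.knee_index - 0.5, color="black", linestyle="--", lw=1)
        ax.set_xlabel("importance (inverted weighted rank score)")
        return ax


def _final_estimator(model):
    return model.steps[-1][1] if isinstance(model, Pipeline) else model


def _encoded_column_importance(
    tuned: TunedLearner,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Per-encoded-column importance using the learner's native measure.

    Linear models: |coefficient| on standardized inputs (hinge expansions
    are summed back to their source column).  Trees/forests: impurity
    reduction.  Otherwise: AUC permutation importance.
    """
    model = tuned.fitted_model
    if model is None:
        raise ValueError(f"learner {tuned.name} has no fitted model")
    X = np.asarray(X, dtype=float)
    n_cols = X.shape[1]
    final = _final_estimator(model)

    if hasattr(final, "coef_"):
        coefs = np.abs(np.ravel(final.coef_))
        if isinstance(model, Pipeline):
            for _, step in model.steps:
                if isinstance(step, HingeFeatures):
                    out = np.zeros(n_cols)
                    np.add.at(out, step.output_to_input_, coefs)
                    return out
        if len(coefs) != n_cols:
            raise ValueError(
                f"{tuned.name}: {len(coefs)} coefficients for {n_cols} columns"
            )
        return coefs
    if hasattr(final, "feature_importances_"):
        return np.asarray(final.feature_importances_, dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = permutation_importance(
            model, X, y, scoring="roc_auc", n_repeats=3, random_state=seed
        )
    return np.clip(result.importances_mean, 0.0, None)


def per_learner_importance(
    tuned: TunedLearner,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    encoder: FeatureEncoder,
    seed: int = 0,
) -> pd.Series:
    """Nonnegative importance per original schema feature.

    One-hot (and hinge-expanded) columns are summed back to their parent
    feature via the encoder's group map.
    """
    col_imp = _encoded_column_importance(tuned, X, y, seed=seed)
    out = {}
    for feature, cols in encoder.groups_.items():
        out[feature] = float(col_imp[cols].sum()) if cols else 0.0
    return pd.Series(out, name=tuned.name)


def aggregate_ranks(
    importances: pd.DataFrame,
    meta_weights: dict[str, float],
) -> tuple[pd.Series, pd.DataFrame, dict[str, float]]:
    """Weighted sum rank aggregation across learners.

    ``importances`` is features x learners.  Within each learner, features
    are ranked 1 (most important) to p with average ranks for ties; each
    learner's share is its |meta coefficient| normalized to sum to one;
    the aggregated score is the share-weighted rank sum, ascending = best.

    Returns ``(scores sorted ascending with alphabetical tie-break,
    rank table, shares)``.
    """
    learners = [c for c in importances.columns if c in meta_weights]
    if not learners:
        raise ValueError("no learner columns matching meta weights")
    abs_w = np.array([abs(meta_weights[c]) for c in learners])
    if abs_w.sum() == 0:
        warnings.warn(
            "all meta coefficients are zero; using equal learner shares",
            stacklevel=2,
        )
        abs_w = np.ones(len(learners))
    shares = {c: w / abs_w.sum() for c, w in zip(learners, abs_w)}

    ranks = pd.DataFrame(
        {c: rankdata(-importances[c].to_numpy()) for c in learners},
        index=importances.index,
    )
    scores = sum(shares[c] * ranks[c] for c in learners)
    order = sorted(scores.index, key=lambda f: (scores[f], f))
    return scores.loc[order], ranks, shares


def knee_point(sorted_scores: np.ndarray | pd.Series) -> tuple[int, bool]:
    """Two-line knee of an ascending score sequence.

    For each split ``s`` in ``2..p-2`` (first segment = positions 1..s),
    fit a least-squares line to each segment; the knee is the split
    minimizing the total residual sum of squares, ties resolved to the
    smallest split.  Returns ``(knee_index, no_clear_knee)`` where the flag
    marks tied (degenerate) fits.  For p < 4 the knee is p with a warning.
    """
    scores = np.asarray(sorted_scores, dtype=float)
    p = len(scores)
    if p < 4:
        warnings.warn(
            f"knee point undefined for p={p} < 4; returning p", stacklevel=2
        )
        return p, True
    x = np.arange(1, p + 1, dtype=float)
    candidates = range(2, p - 1)  # s = 2..p-2 so both segments have >= 2 points
    rss = []
    for s in candidates:
        rss.append(_line_rss(x[:s], scores[:s]) + _line_rss(x[s:], scores[s:]))
    rss = np.asarray(rss)
    best = int(np.argmin(rss))
    tied = np.flatnonzero(rss <= rss[best] + 1e-12)
    no_clear = len(tied) > 1
    if no_clear:
        logger.info("knee RSS tie among splits %s; taking smallest", (tied + 2).tolist())
    return int(tied[0]) + 2, no_clear


def _line_rss(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the least-squares line through (x, y)."""
    coeffs, res, *_ = np.polyfit(x, y, 1, full=True)
    if len(res):
        return float(res[0])
    fit = np.polyval(coeffs, x)
    return float(((y - fit) ** 2).sum())


def assign_directions(
    lgr_learner: TunedLearner | None,
    encoder: FeatureEncoder,
    schema: FeatureSchema,
) -> dict[str, str]:
    """Per-feature sign labels from the logistic-regression base learner.

    Continuous, ordinal, and binary-categorical features get the sign of
    their (single) coefficient; multi-level categoricals are labeled
    ``categorical``.  Without an LGR-role learner, all features are labeled
    ``unsigned`` with a warning.
    """
    if lgr_learner is None or lgr_learner.fitted_model is None:
        warnings.warn(
            "no logistic-regression learner available; directions unsigned",
            stacklevel=2,
        )
        return {f: "unsigned" for f in schema.feature_names}
    final = _final_estimator(lgr_learner.fitted_model)
    if not isinstance(final, LogisticRegression):
        raise ValueError("direction assignment requires a logistic-regression learner")
    coefs = np.ravel(final.coef_)
    directions = {}
    for name, kind in zip(schema.feature_names, schema.feature_kinds):
        cols = encoder.groups_[name]
        if kind == "categorical" and len(cols) > 1:
            directions[name] = "categorical"
        elif len(cols) != 1:
            directions[name] = "unsigned"
        else:
            c = coefs[cols[0]]
            directions[name] = "positive" if c >= 0 else "negative"
    return directions


def build_importance_table(
    tuned_survivors: list[TunedLearner],
    meta_weights: dict[str, float],
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    encoder: FeatureEncoder,
    schema: FeatureSchema,
    lgr_learner: TunedLearner | None = None,
    seed: int = 0,
) -> ImportanceTable:
    """End-to-end importance report for an ensemble."""
    importances = pd.DataFrame(
        {t.name: per_learner_importance(t, X, y, encoder, seed=seed) for t in tuned_survivors}
    )
    scores, ranks, shares = aggregate_ranks(importances, meta_weights)
    knee, no_clear = knee_point(scores.to_numpy())
    directions = assign_directions(lgr_learner, encoder, schema)
    return ImportanceTable(
        feature_names=list(scores.index),
        per_learner_ranks=ranks,
        meta_weight_share=shares,
        aggregated_score=scores,
        knee_index=knee,
        direction=directions,
        no_clear_knee=no_clear,
    )
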