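"""Meta-classifier stacking over the surviving base learners.

The meta-classifier (logistic regression by default) is trained on the
survivors' out-of-fold probabilities — predictions made by models that never
saw the case — so the meta fit measures genuine complementarity rather than
base-model overfit.  At predict time each base model scores the new data and
the meta model maps the score vector to one probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass
class EnsembleModel:
    """Survivor names, fitted base models, and the meta-classifier weights."""

    survivors: tuple[str, ...]
    meta_kind: str
    meta_model: BaseEstimator
    meta_weights: dict[str, float]
    meta_intercept: float
    base_models: dict[str, BaseEstimator]
    penalized: bool = False

    def __post_init__(self) -> None:
        if set(self.meta_weights) != set(self.survivors):
            raise ValueError("one meta weight required per survivor")


def fit_meta(
    oof_matrix: np.ndarray,
    labels: np.ndarray,
    survivor_names: Sequence[str],
    base_models: Mapping[str, BaseEstimator] | None = None,
    meta_kind: str = "lgr",
) -> EnsembleModel:
    """Fit the meta-classifier on survivors' OOF probabilities.

    ``oof_matrix`` must already be restricted to the survivor columns, in
    order.  The default (and only) meta kind is logistic regression, fitted
    near-unpenalized; on perfect separation / non-convergence it falls back
    to a ridge-penalized fit with a warning.
    """
    if meta_kind != "lgr":
        raise ValueError(f"unsupported meta kind {meta_kind!r}")
    names = tuple(survivor_names)
    X = np.asarray(oof_matrix, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("oof_matrix must have one column per survivor")
    if len(names) < 1:
        raise ValueError("need at least one survivor")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    penalized = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        meta = LogisticRegression(C=1e6, max_iter=2000).fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            penalized = True
    if penalized:
        warnings.warn(
            "meta fit did not converge unpenalized (separation or collinearity); "
            "falling back to ridge-penalized logistic regression",
            stacklevel=2,
        )
        meta = LogisticRegression(C=1.0, max_iter=2000).fit(X, y)

    weights = dict(zip(names, meta.coef_[0].tolist()))
    return EnsembleModel(
        survivors=names,
        meta_kind=meta_kind,
        meta_model=meta,
        meta_weights=weights,
        meta_intercept=float(meta.intercept_[0]),
        base_models=dict(base_models or {}),
        penalized=penalized,
    )


def base_probability_matrix(
    model: EnsembleModel, X: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Each survivor's positive-class probabilities on new encoded data."""
    X = np.asarray(X, dtype=float)
    cols = []
    for name in model.survivors:
        base = model.base_models.get(name)
        if base is None:
            raise RuntimeError(f"no fitted base model stored for learner {name!r}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cols.append(base.predict_proba(X)[:, 1])
        except Exception as exc:
            raise RuntimeError(f"base model {name!r} failed at predict time") from exc
    return np.column_stack(cols)


def predict_ensemble(
    model: EnsembleModel, X: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Ensemble positive-class probability per row of the encoded data."""
    probs = base_probability_matrix(model, X)
    return model.meta_model.predict_proba(probs)[:, 1]
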