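"""Base-classifier bank: registry, random hyper-parameter search, OOF collection.

Each base classifier is tuned by sampling ``m`` hyper-parameter sets
uniformly from its declared space and scoring each by mean AUC under
``repeats`` x ``k``-fold stratified CV with in-fold minority upsampling.
All learners share one fold plan so their out-of-fold (OOF) probability
vectors are aligned — the prerequisite for honest stacking.

The published learner set is R-specific (conditional inference trees,
evolutionary trees, logistic model trees, C5.0 rule trees, MARS).  The
registry ships faithful scikit-learn equivalents where they exist and
documented stand-ins otherwise; the removal/stacking/importance algorithms
are learner-agnostic.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hyper-parameter samplers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))


@dataclass(frozen=True)
class LogUniform:
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))


@dataclass(frozen=True)
class IntUniform:
    lo: int
    hi: int

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.lo, self.hi + 1))


@dataclass(frozen=True)
class Choice:
    options: tuple

    def sample(self, rng: np.random.Generator):
        return self.options[int(rng.integers(len(self.options)))]


Sampler = Uniform | LogUniform | IntUniform | Choice


# ---------------------------------------------------------------------------
# helper estimators
# ---------------------------------------------------------------------------


class ScoreToProbability(BaseEstimator, ClassifierMixin):
    """Wrap a margin classifier: decision values mapped through the logistic.

    Calibration-free; used for learners that do not expose probabilities
    natively (flagged in their spec).
    """

    def __init__(self, base: BaseEstimator):
        self.base = base

    def fit(self, X, y):
        self.base_ = clone(self.base).fit(X, y)
        self.classes_ = self.base_.classes_
        return self

    def decision_function(self, X):
        return self.base_.decision_function(X)

    def predict_proba(self, X):
        p1 = expit(self.base_.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.base_.predict(X)


class HingeFeatures(BaseEstimator):
    """Piecewise-linear basis expansion: paired hinges at quantile knots.

    For every input column, emits ``max(x - k, 0)`` and ``max(k - x, 0)``
    at ``n_knots`` empirical quantiles (plus the raw column).  Combined with
    a linear model this gives an adaptive-spline regression surface — the
    stand-in for a MARS learner.  ``output_to_input_`` maps each emitted
    column back to its source column.
    """

    def __init__(self, n_knots: int = 4):
        self.n_knots = n_knots

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        self.knots_ = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]
        mapping = []
        for j in range(X.shape[1]):
            mapping.append(j)  # raw column
            mapping.extend([j] * (2 * len(self.knots_[j])))
        self.output_to_input_ = np.array(mapping)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        parts = []
        for j in range(X.shape[1]):
            parts.append(X[:, j : j + 1])
            for k in self.knots_[j]:
                parts.append(np.maximum(X[:, j : j + 1] - k, 0.0))
                parts.append(np.maximum(k - X[:, j : j + 1], 0.0))
        return np.hstack(parts)

    def get_params(self, deep=True):
        return {"n_knots": self.n_knots}


# ---------------------------------------------------------------------------
# learner registry
# ---------------------------------------------------------------------------


@dataclass
class LearnerSpec:
    """A registered base-classifier role.

    ``factory(params, seed)`` returns an unfitted estimator;
    ``hyper_space`` maps hyper-parameter names to samplers.
    """

    name: str
    factory: Callable[[Mapping, int], BaseEstimator]
    hyper_space: dict[str, Sampler]
    produces_probabilities: bool = True

    def sample_params(self, rng: np.random.Generator) -> dict:
        return {k: s.sample(rng) for k, s in self.hyper_space.items()}


def _lgr_factory(params: Mapping, seed: int) -> BaseEstimator:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=params["C"], max_iter=2000)),
        ]
    )


def _mars_factory(params: Mapping, seed: int) -> BaseEstimator:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("hinge", HingeFeatures(n_knots=params["n_knots"])),
            ("clf", LogisticRegression(C=params["C"], max_iter=2000)),
        ]
    )


def _cart_factory(params: Mapping, seed: int) -> BaseEstimator:
    return DecisionTreeClassifier(
        criterion="gini",
        max_depth=params["max_depth"],
        min_samples_leaf=params["min_samples_leaf"],
        random_state=seed,
    )


def _ctree_factory(params: Mapping, seed: int) -> BaseEstimator:
    # stand-in for conditional inference trees: entropy splits, pruned
    return DecisionTreeClassifier(
        criterion="entropy",
        max_depth=params["max_depth"],
        min_samples_leaf=params["min_samples_leaf"],
        ccp_alpha=params["ccp_alpha"],
        random_state=seed,
    )


def _evtree_factory(params: Mapping, seed: int) -> BaseEstimator:
    # stand-in for globally-searched trees: a single extra-randomized tree
    return ExtraTreeClassifier(
        max_depth=params["max_depth"],
        min_samples_leaf=params["min_samples_leaf"],
        random_state=seed,
    )


def _c50_factory(params: Mapping, seed: int) -> BaseEstimator:
    # stand-in for boosted rule trees: gradient-boosted shallow trees
    return GradientBoostingClassifier(
        n_estimators=params["n_estimators"],
        learning_rate=params["learning_rate"],
        max_depth=params["max_depth"],
        random_state=seed,
    )


def _lmt_factory(params: Mapping, seed: int) -> BaseEstimator:
    # stand-in for logistic model trees: shallow additive boosting on logits
    return HistGradientBoostingClassifier(
        max_iter=params["max_iter"],
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        random_state=seed,
    )


def _rf_factory(params: Mapping, seed: int) -> BaseEstimator:
    return RandomForestClassifier(
        n_estimators=params["n_estimators"],
        max_features=params["max_features"],
        min_samples_leaf=params["min_samples_leaf"],
        random_state=seed,
        n_jobs=1,
    )


def _bpnn_factory(params: Mapping, seed: int) -> BaseEstimator:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                MLPClassifier(
                    hidden_layer_sizes=(params["hidden_units"],),
                    alpha=params["alpha"],
                    max_iter=150,
                    random_state=seed,
                ),
            ),
        ]
    )


def _svm_factory(params: Mapping, seed: int) -> BaseEstimator:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                ScoreToProbability(
                    SVC(C=params["C"], gamma=params["gamma"], kernel="rbf")
                ),
            ),
        ]
    )


def default_registry() -> dict[str, LearnerSpec]:
    """Ten base-classifier roles with conventional wide hyper-spaces."""
    return {
        "lgr": LearnerSpec(
            "lgr", _lgr_factory, {"C": LogUniform(1e-3, 1e3)}
        ),
        "mars": LearnerSpec(
            "mars",
            _mars_factory,
            {"n_knots": IntUniform(2, 6), "C": LogUniform(1e-3, 1e2)},
        ),
        "cart": LearnerSpec(
            "cart",
            _cart_factory,
            {"max_depth": IntUniform(2, 12), "min_samples_leaf": IntUniform(5, 100)},
        ),
        "ctree": LearnerSpec(
            "ctree",
            _ctree_factory,
            {
                "max_depth": IntUniform(2, 12),
                "min_samples_leaf": IntUniform(5, 100),
                "ccp_alpha": LogUniform(1e-5, 1e-2),
            },
        ),
        "evtree": LearnerSpec(
            "evtree",
            _evtree_factory,
            {"max_depth": IntUniform(3, 14), "min_samples_leaf": IntUniform(5, 100)},
        ),
        "c50": LearnerSpec(
            "c50",
            _c50_factory,
            {
                "n_estimators": IntUniform(30, 150),
                "learning_rate": LogUniform(0.02, 0.5),
                "max_depth": IntUniform(1, 3),
            },
        ),
        "lmt": LearnerSpec(
            "lmt",
            _lmt_factory,
            {
                "max_iter": IntUniform(30, 150),
                "max_depth": IntUniform(2, 4),
                "learning_rate": LogUniform(0.02, 0.5),
            },
        ),
        "rf": LearnerSpec(
            "rf",
            _rf_factory,
            {
                "n_estimators": IntUniform(50, 200),
                "max_features": Choice(("sqrt", "log2", None)),
                "min_samples_leaf": IntUniform(1, 20),
            },
        ),
        "bpnn": LearnerSpec(
            "bpnn",
            _bpnn_factory,
            {"hidden_units": IntUniform(4, 32), "alpha": LogUniform(1e-5, 1e-1)},
        ),
        "svm": LearnerSpec(
            "svm",
            _svm_factory,
            {"C": LogUniform(1e-2, 1e2), "gamma": LogUniform(1e-3, 1.0)},
            produces_probabilities=False,
        ),
    }


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TuningConfig:
    """Random-search budget: m candidates, repeats x k-fold CV, AUC metric."""

    m: int = 30
    k: int = 10
    repeats: int = 3
    metric: str = "auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.metric != "auc":
            raise ValueError("only the AUC selection metric is supported")


@dataclass(frozen=True)
class FoldPlan:
    """Shared CV fold assignment — identical across all learners in a bank."""

    folds: tuple[tuple[np.ndarray, np.ndarray], ...]
    k: int
    repeats: int
    seed: int

    @classmethod
    def create(cls, labels: np.ndarray, cfg: TuningConfig) -> "FoldPlan":
        splitter = RepeatedStratifiedKFold(
            n_splits=cfg.k, n_repeats=cfg.repeats, random_state=cfg.seed
        )
        folds = tuple(
            (tr.copy(), te.copy())
            for tr, te in splitter.split(np.zeros(len(labels)), labels)
        )
        return cls(folds=folds, k=cfg.k, repeats=cfg.repeats, seed=cfg.seed)

    @property
    def fingerprint(self) -> int:
        h = zlib.crc32(f"{self.k}:{self.repeats}:{self.seed}".encode())
        for tr, te in self.folds:
            h = zlib.crc32(te.tobytes(), h)
        return h


@dataclass
class TunedLearner:
    """A tuned base classifier with its CV record and OOF predictions.

    ``oof_probs`` holds one positive-class probability per training case,
    averaged over CV repeats; missing predictions are NaN.
    """

    spec: LearnerSpec
    chosen_params: dict
    cv_auc: float
    oof_probs: np.ndarray
    fitted_model: BaseEstimator | None
    candidates: list[dict] = field(default_factory=list)
    fold_fingerprint: int = 0

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n_missing_oof(self) -> int:
        return int(np.isnan(self.oof_probs).sum())


def _upsample_xy(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """In-fold minority upsampling (mirrors cohort.upsample_minority)."""
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2 or counts[0] == counts[1]:
        return X, y
    minority = values[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


def _learner_seed(base_seed: int, name: str, salt: int = 0) -> int:
    return zlib.crc32(f"{base_seed}:{name}:{salt}".encode()) % (2**31)


def random_search_tune(
    spec: LearnerSpec,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: TuningConfig,
    fold_plan: FoldPlan | None = None,
) -> TunedLearner:
    """Tune one base classifier by random search under repeated CV.

    For each of ``cfg.m`` sampled hyper-parameter sets, runs
    ``repeats x k`` CV with in-fold minority upsampling and scores the mean
    AUC; selects the argmax and refits it on the full (upsampled) training
    data.  A candidate whose fit fails on any fold is scored missing; if
    every candidate is missing the learner is returned marked failed
    (``cv_auc`` NaN, ``fitted_model`` None).

    Deterministic for a fixed ``cfg.seed`` (per-learner streams are derived
    from the seed and the learner name).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if fold_plan is None:
        fold_plan = FoldPlan.create(y, cfg)
    rng = np.random.default_rng(_learner_seed(cfg.seed, spec.name))
    est_seed = _learner_seed(cfg.seed, spec.name, salt=1)

    n = len(y)
    n_folds = len(fold_plan.folds)
    candidates: list[dict] = []
    best_score = -np.inf
    best: dict | None = None
    best_oof: np.ndarray | None = None

    for ci in range(cfg.m):
        params = spec.sample_params(rng)
        fold_aucs = np.full(n_folds, np.nan)
        oof_sum = np.zeros(n)
        oof_cnt = np.zeros(n)
        failed = False
        for fi, (tr, te) in enumerate(fold_plan.folds):
            up_rng = np.random.default_rng(
                _learner_seed(cfg.seed, spec.name, salt=1000 + fi)
            )
            Xtr, ytr = _upsample_xy(X[tr], y[tr], up_rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = spec.factory(params, est_seed)
                    model.fit(Xtr, ytr)
                    probs = model.predict_proba(X[te])[:, 1]
            except Exception as exc:  # noqa: BLE001 — any fit failure voids the candidate
                logger.debug("%s candidate %d failed on fold %d: %s", spec.name, ci, fi, exc)
                failed = True
                break
            good = ~np.isnan(probs)
            oof_sum[te[good]] += probs[good]
            oof_cnt[te[good]] += 1
            if good.all() and len(np.unique(y[te])) == 2:
                fold_aucs[fi] = roc_auc_score(y[te], probs)
        score = np.nan if failed or np.isnan(fold_aucs).all() else float(
            np.nanmean(fold_aucs)
        )
        candidates.append({"params": params, "mean_auc": score})
        if not np.isnan(score) and score > best_score:
            best_score = score
            best = params
            with np.errstate(invalid="ignore"):
                best_oof = np.where(oof_cnt > 0, oof_sum / oof_cnt, np.nan)

    if best is None:
        logger.warning("learner %s failed on all %d candidates", spec.name, cfg.m)
        return TunedLearner(
            spec=spec,
            chosen_params={},
            cv_auc=float("nan"),
            oof_probs=np.full(n, np.nan),
            fitted_model=None,
            candidates=candidates,
            fold_fingerprint=fold_plan.fingerprint,
        )

    refit_rng = np.random.default_rng(_learner_seed(cfg.seed, spec.name, salt=2))
    Xu, yu = _upsample_xy(X, y, refit_rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = spec.factory(best, est_seed)
        fitted.fit(Xu, yu)

    return TunedLearner(
        spec=spec,
        chosen_params=best,
        cv_auc=best_score,
        oof_probs=best_oof,
        fitted_model=fitted,
        candidates=candidates,
        fold_fingerprint=fold_plan.fingerprint,
    )


def tune_bank(
    registry: Mapping[str, LearnerSpec],
    names: Sequence[str],
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: TuningConfig,
) -> list[TunedLearner]:
    """Tune several learners against one shared fold plan."""
    plan = FoldPlan.create(np.asarray(y), cfg)
    tuned = []
    for name in names:
        logger.info("tuning %s (m=%d, %dx%d-fold CV)", name, cfg.m, cfg.repeats, cfg.k)
        tuned.append(random_search_tune(registry[name], X, y, cfg, fold_plan=plan))
    return tuned


def collect_oof_predictions(tuned: Sequence[TunedLearner]) -> np.ndarray:
    """Stack aligned OOF probability columns into an ``n x l`` matrix.

    Raises if the learners were tuned under different fold assignments.
    """
    if not tuned:
        raise ValueError("no tuned learners given")
    fps = {t.fold_fingerprint for t in tuned}
    if len(fps) > 1:
        raise ValueError("misaligned fold assignments across learners")
    lengths = {len(t.oof_probs) for t in tuned}
    if len(lengths) > 1:
        raise ValueError("OOF vectors have inconsistent lengths")
    return np.column_stack([t.oof_probs for t in tuned])


def eject_invalid_learners(
    tuned: Sequence[TunedLearner],
) -> tuple[list[TunedLearner], list[dict]]:
    """Remove learners with any missing OOF prediction before correlation
    analysis.  Returns (survivors, ejection log)."""
    survivors: list[TunedLearner] = []
    log: list[dict] = []
    for t in tuned:
        n_missing = t.n_missing_oof
        if n_missing > 0 or t.fitted_model is None:
            log.append({"name": t.name, "n_missing": n_missing})
            logger.info(
                "ejecting learner %s: %d missing OOF predictions", t.name, n_missing
            )
        else:
            survivors.append(t)
    if not survivors:
        raise RuntimeError("all learners ejected: no valid OOF predictions remain")
    return survivors, log
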