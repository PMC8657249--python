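"""Registry-shaped synthetic cohorts with planted, heterogeneous signal.

The real cohort behind this tool is IRB-gated, so everything downstream is
exercised on simulated data whose shape matches a cancer-registry extract:
~27k rows, ~12% event prevalence, 14 mixed-type predictors.  Signal is split
across a linear part, a threshold nonlinearity, and an interaction so that
linear and tree-based learners genuinely capture different aspects.

Also provides :func:`generate_prediction_bank`, a Gaussian-copula generator
of pseudo-learner probability vectors with a prescribed inter-learner
correlation structure — the fixture for testing the removal scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from stackprune.cohort import CohortTable, FeatureSchema


class CalibrationError(RuntimeError):
    """Target prevalence unreachable for the given signal configuration."""


#: Generator recipes for the default 14-feature registry-like schema.
#: kind, then sampling rule.  Names mirror common cancer-registry variables
#: purely so reports read naturally; the joint distribution is synthetic.
_DEFAULT_FEATURES: dict[str, dict] = {
    "age_at_diagnosis": {"kind": "continuous", "dist": ("normal", 55.0, 12.0)},
    "sex": {"kind": "categorical", "levels": ["female", "male"], "probs": [0.25, 0.75]},
    "primary_site": {
        "kind": "categorical",
        "levels": ["hypopharynx", "larynx", "oral_cavity", "oropharynx"],
        "probs": [0.15, 0.2, 0.45, 0.2],
    },
    "clinical_stage": {"kind": "ordinal", "levels": [1, 2, 3, 4], "probs": [0.2, 0.25, 0.25, 0.3]},
    "pathologic_stage": {"kind": "ordinal", "levels": [1, 2, 3, 4], "probs": [0.25, 0.25, 0.25, 0.25]},
    "combined_stage": {"kind": "ordinal", "levels": [1, 2, 3, 4], "probs": [0.2, 0.25, 0.25, 0.3]},
    "surgical_margins": {
        "kind": "categorical",
        "levels": ["clear", "involved"],
        "probs": [0.8, 0.2],
    },
    "lymph_node_size": {"kind": "continuous", "dist": ("lognormal", 0.5, 0.6)},
    "surgery_interval_days": {"kind": "continuous", "dist": ("exponential", 30.0)},
    "rt_surgery_sequence": {
        "kind": "categorical",
        "levels": ["none", "rt_first", "surgery_first"],
        "probs": [0.3, 0.3, 0.4],
    },
    "therapy_sequence": {
        "kind": "categorical",
        "levels": ["concurrent", "sequential", "single"],
        "probs": [0.3, 0.3, 0.4],
    },
    "ctv_low_dose": {"kind": "continuous", "dist": ("normal", 5000.0, 800.0)},
    "node_level_involvement": {"kind": "ordinal", "levels": [0, 1, 2, 3], "probs": [0.5, 0.2, 0.2, 0.1]},
    "bmi": {"kind": "continuous", "dist": ("normal", 24.0, 4.0)},
}


def default_schema(outcome_name: str = "event") -> FeatureSchema:
    """The default 14-feature mixed-type schema."""
    return FeatureSchema(
        feature_names=tuple(_DEFAULT_FEATURES),
        feature_kinds=tuple(v["kind"] for v in _DEFAULT_FEATURES.values()),
        outcome_name=outcome_name,
    )


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic cohort.

    ``linear_coefs`` are signed weights on standardized numeric codes;
    ``nonlinear_terms`` are ``(feature, transform, weight)`` with transform
    in ``{"threshold", "square", "abs"}``; ``interaction_terms`` are
    ``(feature_a, feature_b, weight)`` products of standardized codes.
    """

    n: int = 5000
    prevalence: float = 0.1226
    schema: FeatureSchema = field(default_factory=default_schema)
    linear_coefs: dict[str, float] = field(default_factory=dict)
    nonlinear_terms: list[tuple[str, str, float]] = field(default_factory=list)
    interaction_terms: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        known = set(self.schema.feature_names)
        used = set(self.linear_coefs)
        used.update(f for f, _, _ in self.nonlinear_terms)
        for a, b, _ in self.interaction_terms:
            used.update((a, b))
        unknown = used - known
        if unknown:
            raise ValueError(f"signal references unknown features: {sorted(unknown)}")

    @property
    def informative_features(self) -> tuple[str, ...]:
        """Features carrying nonzero weight in any signal component."""
        inf: set[str] = {f for f, w in self.linear_coefs.items() if w != 0}
        inf.update(f for f, _, w in self.nonlinear_terms if w != 0)
        for a, b, w in self.interaction_terms:
            if w != 0:
                inf.update((a, b))
        return tuple(f for f in self.schema.feature_names if f in inf)


def default_signal_config(
    n: int = 5000, prevalence: float = 0.1226, seed: int = 0, noise_sd: float = 1.0
) -> SyntheticConfig:
    """Canonical 6-informative / 8-null configuration.

    Signal is deliberately heterogeneous so different learner families have
    different blind spots: four additive linear effects (where linear models
    excel), one threshold effect, and one near-pure interaction (where trees
    and networks excel).  No single learner family captures everything,
    which is what makes stacking complementary learners worthwhile.
    """
    return SyntheticConfig(
        n=n,
        prevalence=prevalence,
        linear_coefs={
            "bmi": -0.65,
            "sex": 0.65,
            "node_level_involvement": 0.6,
            "age_at_diagnosis": 0.45,
        },
        nonlinear_terms=[("lymph_node_size", "threshold", 1.3)],
        interaction_terms=[("age_at_diagnosis", "combined_stage", 1.5)],
        noise_sd=noise_sd,
        seed=seed,
    )


def _draw_feature(name: str, spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec["kind"]
    if kind == "continuous":
        dist = spec["dist"]
        if dist[0] == "normal":
            return rng.normal(dist[1], dist[2], size=n)
        if dist[0] == "lognormal":
            return rng.lognormal(dist[1], dist[2], size=n)
        if dist[0] == "exponential":
            return rng.exponential(dist[1], size=n)
        raise ValueError(f"unknown distribution {dist[0]!r} for {name!r}")
    return rng.choice(spec["levels"], size=n, p=spec["probs"])


def _numeric_codes(values: np.ndarray, spec: dict) -> np.ndarray:
    """Standardized numeric representation used by the signal model."""
    if spec["kind"] == "continuous":
        x = values.astype(float)
    else:
        levels = spec["levels"]
        lookup = {lv: i for i, lv in enumerate(levels)}
        x = np.array([lookup[v] for v in values], dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _apply_transform(z: np.ndarray, transform: str) -> np.ndarray:
    if transform == "threshold":
        return (z > 0.5).astype(float)
    if transform == "square":
        return z**2
    if transform == "abs":
        return np.abs(z)
    raise ValueError(f"unknown nonlinear transform {transform!r}")


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Bisect the intercept so mean predicted probability hits *prevalence*."""
    lo, hi = -30.0, 30.0
    if expit(eta + lo).mean() > prevalence or expit(eta + hi).mean() < prevalence:
        raise CalibrationError(
            f"prevalence {prevalence} unreachable within intercept bounds"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(eta + mid).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    config: SyntheticConfig,
    feature_recipes: dict[str, dict] | None = None,
) -> tuple[CohortTable, dict]:
    """Draw a cohort and its ground-truth record.

    Labels are Bernoulli(sigmoid(intercept + linear + nonlinear +
    interaction + noise)); the intercept is calibrated by bisection so the
    expected prevalence equals the target.  The ground-truth record lists
    informative features with their planted signs.
    """
    recipes = feature_recipes or _DEFAULT_FEATURES
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    columns: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for name in schema.feature_names:
        spec = recipes[name]
        values = _draw_feature(name, spec, config.n, rng)
        columns[name] = values
        codes[name] = _numeric_codes(values, spec)

    eta = np.zeros(config.n)
    for name, w in config.linear_coefs.items():
        eta += w * codes[name]
    for name, transform, w in config.nonlinear_terms:
        eta += w * _apply_transform(codes[name], transform)
    for a, b, w in config.interaction_terms:
        eta += w * codes[a] * codes[b]
    if config.noise_sd > 0:
        eta += rng.normal(0.0, config.noise_sd, size=config.n)

    intercept = _calibrate_intercept(eta, config.prevalence)
    probs = expit(eta + intercept)
    labels = rng.binomial(1, probs)

    signs = {}
    for name in config.informative_features:
        w = config.linear_coefs.get(name, 0.0)
        if w == 0.0:
            for f, transform, wt in config.nonlinear_terms:
                if f == name and transform == "threshold":
                    w = wt
        signs[name] = "positive" if w > 0 else ("negative" if w < 0 else "mixed")

    truth = {
        "informative_features": list(config.informative_features),
        "signs": signs,
        "intercept": intercept,
        "realized_prevalence": float(labels.mean()),
    }
    table = CohortTable(
        schema=schema, records=pd.DataFrame(columns), labels=labels
    )
    return table, truth


def generate_prediction_bank(
    l: int,
    n: int,
    target_corr: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus ``l`` pseudo-learner probability vectors with a target
    inter-learner correlation structure.

    Gaussian copula: draw latent N(0, target_corr) rows, push each margin
    through the logistic function.  Empirical pairwise correlations match
    the target within about ±0.05 for n >= 2000.

    Returns ``(labels, probs)`` where ``probs`` is ``n x l``.
    """
    target = np.asarray(target_corr, dtype=float)
    if target.shape != (l, l):
        raise ValueError(f"target_corr must be {l}x{l}, got {target.shape}")
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target_corr must be symmetric")
    if not np.allclose(np.diag(target), 1.0, atol=1e-10):
        raise ValueError("target_corr must have unit diagonal")
    eigvals = np.linalg.eigvalsh(target)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"target_corr is not positive semidefinite: eigenvalue {eigvals.min():.6g}"
        )
    rng = np.random.default_rng(seed)
    # eigen factorization tolerates the semidefinite boundary (unlike Cholesky)
    w, v = np.linalg.eigh(target)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, l)) @ factor.T
    probs = expit(z)
    labels = rng.binomial(1, probs.mean(axis=1))
    return labels, probs
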