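"""The data-processing-unit learner: a random-forest classifier with
posterior probabilities, per-label uncertainty, and query strategies.

A random forest serves double duty here.  It is the activity classifier, and
its committee structure yields two informativeness measures for pool-based
active learning:

* **entropy** — the Shannon entropy of the posterior, −Σᵢ p(ℓᵢ|x) ln p(ℓᵢ|x);
  the instance minimizing Σ p ln p (equivalently maximizing entropy) is the
  most informative one;
* **leaf purity** — one minus the mean, over trees, of the fraction of
  training samples of the majority class in the leaf the instance falls in;
  a committee-disagreement score that is 0 when every leaf is pure.

The ``hybrid`` strategy averages the two scores after min–max normalization
over the candidate pool; ``random`` is the baseline used by random active
learning (RAL).
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data import Dictionary, FeatureInstance, InputError, UncertaintyVector

__all__ = [
    "RandomForestLearner",
    "entropy_informativeness",
    "leaf_purity_informativeness",
    "get_informative_instances",
    "learner_uncertainty",
    "TrainingError",
]

Strategy = Literal["entropy", "leaf_purity", "hybrid", "random"]


class TrainingError(ValueError):
    pass


class NotTrainedError(RuntimeError):
    pass


class RandomForestLearner:
    """Random-forest classifier wrapper with a stable label space.

    10 estimators by default; remaining hyperparameters are the library
    defaults, pinned here only through the seed for reproducibility.
    """

    def __init__(self, n_estimators: int = 10, seed: int = 0) -> None:
        self.n_estimators = int(n_estimators)
        self.seed = int(seed)
        self._forest: Optional[RandomForestClassifier] = None
        self.label_space: list[str] = []

    @property
    def is_trained(self) -> bool:
        return self._forest is not None

    def fit(self, labeled: Dictionary) -> "RandomForestLearner":
        if len(labeled) == 0:
            raise TrainingError("cannot fit on an empty pool")
        y = labeled.y
        if any(lab is None for lab in y):
            raise TrainingError("all training instances must be labeled")
        self._forest = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed
        )
        self._forest.fit(labeled.X, np.asarray(y, dtype=object))
        self.label_space = [str(c) for c in self._forest.classes_]
        return self

    def _require_trained(self) -> RandomForestClassifier:
        if self._forest is None:
            raise NotTrainedError("model has not been fitted")
        return self._forest

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        """(n, k) posterior over ``label_space``; rows sum to 1."""
        forest = self._require_trained()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return forest.predict_proba(X)

    def predict(self, X: np.ndarray) -> list[str]:
        forest = self._require_trained()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return [str(c) for c in forest.predict(X)]

    def predict_label(self, x: FeatureInstance) -> str:
        """Argmax-posterior label; posterior ties resolve to the
        lexicographically smallest label id."""
        p = self.predict_posterior(x.features[None, :])[0]
        best = np.flatnonzero(p == p.max())
        return min(self.label_space[i] for i in best)

    def accuracy(self, pool: Dictionary) -> float:
        if len(pool) == 0:
            raise InputError("empty evaluation pool")
        preds = self.predict(pool.X)
        return float(np.mean([p == t for p, t in zip(preds, pool.y)]))


def entropy_informativeness(p: Sequence[float]) -> float:
    """Shannon entropy of a posterior, in nats, with 0·ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise InputError("posterior must be nonnegative and sum to 1")
    p = np.clip(p, 0.0, None)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz))) + 0.0  # avoid -0.0


def leaf_purity_informativeness(x: FeatureInstance, model: RandomForestLearner) -> float:
    """1 − mean over trees of the majority-class fraction in x's leaf.

    0 when every tree routes x to a pure leaf; bounded above by 1 − 1/k.
    """
    forest = model._require_trained()
    X = x.features[None, :]
    purities = []
    for tree in forest.estimators_:
        leaf = int(tree.apply(X)[0])
        value = np.asarray(tree.tree_.value[leaf]).ravel()
        purities.append(float(value.max() / value.sum()))
    return float(1.0 - np.mean(purities))


def _pool_scores(
    pool: Dictionary, model: Optional[RandomForestLearner], strategy: str, rng: Optional[np.random.Generator]
) -> np.ndarray:
    n = len(pool)
    if strategy == "random":
        gen = rng if rng is not None else np.random.default_rng(0)
        return gen.random(n)
    if model is None or not model.is_trained:
        raise NotTrainedError("informativeness strategies require a trained model")
    if strategy == "entropy":
        post = model.predict_posterior(pool.X)
        return np.array([entropy_informativeness(row) for row in post])
    if strategy == "leaf_purity":
        return np.array([leaf_purity_informativeness(inst, model) for inst in pool])
    if strategy == "hybrid":
        e = _pool_scores(pool, model, "entropy", rng)
        l = _pool_scores(pool, model, "leaf_purity", rng)

        def norm(v: np.ndarray) -> np.ndarray:
            span = v.max() - v.min()
            return (v - v.min()) / span if span > 0 else np.zeros_like(v)

        return (norm(e) + norm(l)) / 2.0
    raise ValueError(f"unknown strategy {strategy!r}")


def get_informative_instances(
    K: int,
    pool: Dictionary,
    model: Optional[RandomForestLearner] = None,
    strategy: Strategy = "hybrid",
    rng: Optional[np.random.Generator] = None,
) -> list[FeatureInstance]:
    """Top-K pool instances by informativeness, descending; ties break by
    pool insertion order.  K ≥ |pool| returns the whole pool."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(pool) == 0:
        return []
    if K >= len(pool) and strategy != "random":
        return list(pool)
    scores = _pool_scores(pool, model, strategy, rng)
    order = np.argsort(-scores, kind="stable")
    return [pool[int(i)] for i in order[: min(K, len(pool))]]


def learner_uncertainty(
    model: RandomForestLearner,
    pool: Dictionary,
    label_set: Optional[Sequence[str]] = None,
) -> UncertaintyVector:
    """Per-label learner uncertainty over an unlabeled pool, in [0, 100].

    For each label ℓ, u_ℓ = 100 × (1 − mean max-posterior over the pool
    instances the model predicts as ℓ).  A label never predicted — including
    any label outside the model's training label space — gets u_ℓ = 100.
    Needs no target labels, so it can drive the stopping rule online.
    """
    if len(pool) == 0:
        raise InputError("empty pool")
    post = model.predict_posterior(pool.X)
    pred_idx = post.argmax(axis=1)
    conf = post.max(axis=1)
    labels = list(label_set) if label_set is not None else list(model.label_space)
    values = {}
    for lab in labels:
        if lab in model.label_space:
            j = model.label_space.index(lab)
            mask = pred_idx == j
            values[lab] = 100.0 * (1.0 - float(conf[mask].mean())) if mask.any() else 100.0
        else:
            values[lab] = 100.0
    return UncertaintyVector(values)
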