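"""Simulated heterogeneous expert pool: perfect, imperfect, and on-demand.

Three kinds of knowledge source can answer a label query:

* **perfect** — answers from ground truth, with a small configurable error
  probability (a wrong answer is uniform over the other labels); the most
  expensive annotator and the only non-updatable one;
* **imperfect** — a classifier trained on a stratified fraction of the
  expert-initialization data; cheaper, error-prone, updatable;
* **on-demand** — a classifier confident only on a subset of labels
  (trained on all initialization data for those labels plus a few instances
  per other label); free or nearly free, abstains whenever its prediction
  falls outside its confident set; updatable.

Each expert carries an uncertainty score vector (per-label uncertainty
percentage, estimated as the per-label error rate on a held-out evaluation
pool) and a query cost proportional to its mean confidence.  *Collaboration*
broadcasts each round's newly labeled instances to every updatable expert,
which retrains and — after :func:`update_uncertainty_all` — becomes more
confident, shifting future queries toward cheap experts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._rng import substream, substream_seed
from .data import Dictionary, FeatureInstance, UncertaintyVector
from .synthgen import ConfigurationError, split_expert_initialization

__all__ = [
    "Expert",
    "ExpertPool",
    "make_perfect_expert",
    "make_imperfect_expert",
    "make_on_demand_expert",
    "expert_cost_from_confidence",
    "broadcast_labeled_data",
    "update_uncertainty_all",
]

TruthSource = Callable[[FeatureInstance], str]


def expert_cost_from_confidence(uncertainty: UncertaintyVector, base_cost: float) -> float:
    """Query cost proportional to mean confidence:
    ``base_cost × mean_ℓ (100 − u_ℓ)/100``."""
    if base_cost < 0:
        raise ConfigurationError("base_cost must be nonnegative")
    conf = [(100.0 - u) / 100.0 for u in uncertainty.values.values()]
    return float(base_cost * np.mean(conf))


@dataclass
class Expert:
    """One knowledge source in the pool.

    ``unit_cost`` is the charge per query, derived from ``base_cost`` and the
    current uncertainty vector for updatable experts and fixed at
    construction for the perfect expert.
    """

    expert_id: str
    kind: str  # perfect | imperfect | on_demand
    base_cost: float
    uncertainty: UncertaintyVector
    unit_cost: float
    updatable: bool
    label_set: tuple[str, ...]
    confident_labels: frozenset[str] = frozenset()  # on_demand only
    error_rate: float = 0.0  # perfect only
    _truth: Optional[TruthSource] = None
    _model: Optional[RandomForestClassifier] = None
    _train: list[FeatureInstance] = field(default_factory=list)
    _rng: Optional[np.random.Generator] = None
    _model_seed: int = 0

    def query(self, x: FeatureInstance) -> Optional[str]:
        """Answer a label query; ``None`` means abstention (on-demand only)."""
        if self.kind == "perfect":
            true = self._truth(x)
            if self.error_rate > 0 and self._rng.random() < self.error_rate:
                others = [lab for lab in self.label_set if lab != true]
                return str(self._rng.choice(others)) if others else true
            return true
        if self._model is None:  # no training data ever sampled
            return None
        pred = str(self._model.predict(x.features[None, :])[0])
        if self.kind == "on_demand" and pred not in self.confident_labels:
            return None
        return pred

    def raw_predict(self, X: np.ndarray) -> list[str]:
        """Underlying model predictions, ignoring the abstention rule."""
        if self._model is None:
            return ["" for _ in range(np.atleast_2d(X).shape[0])]
        return [str(c) for c in self._model.predict(np.atleast_2d(X))]

    def _retrain(self) -> None:
        if not self._train:
            return
        X = np.vstack([i.features for i in self._train])
        y = np.asarray([i.label for i in self._train], dtype=object)
        self._model = RandomForestClassifier(n_estimators=10, random_state=self._model_seed)
        self._model.fit(X, y)


@dataclass
class ExpertPool:
    experts: list[Expert]
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [e.expert_id for e in self.experts]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("expert ids must be unique")
        for e in self.experts:
            missing = set(self.label_set) - set(e.uncertainty.values)
            if missing:
                raise ConfigurationError(
                    f"expert {e.expert_id} uncertainty vector misses labels {sorted(missing)}"
                )

    def of_kind(self, *kinds: str) -> list[Expert]:
        return [e for e in self.experts if e.kind in kinds]

    def __iter__(self):
        return iter(self.experts)

    def __len__(self) -> int:
        return len(self.experts)


def _per_label_error(
    predict: Callable[[np.ndarray], list[str]],
    eval_pool: Dictionary,
    label_set: Sequence[str],
    trained_labels: Iterable[str],
) -> UncertaintyVector:
    """u_ℓ = 100 × error rate on eval instances of label ℓ; labels the expert
    was never trained on, or absent from the eval pool, get 100."""
    trained = set(trained_labels)
    X, y = eval_pool.X, eval_pool.y
    preds = predict(X) if len(eval_pool) else []
    values = {}
    for lab in label_set:
        if lab not in trained:
            values[lab] = 100.0
            continue
        idx = [i for i, t in enumerate(y) if t == lab]
        if not idx:
            values[lab] = 100.0
            continue
        err = float(np.mean([preds[i] != lab for i in idx]))
        values[lab] = 100.0 * err
    return UncertaintyVector(values)


def make_perfect_expert(
    truth_source: TruthSource,
    error_rate: float,
    unit_cost: float,
    label_set: Sequence[str],
    seed: int = 0,
    expert_id: str = "perfect",
) -> Expert:
    """Ground-truth annotator with flip probability ``error_rate`` (a flipped
    answer is uniform over the other labels).  Not updatable; its cost and
    uncertainty are fixed at construction."""
    if not (0.0 <= error_rate <= 1.0):
        raise ConfigurationError("error_rate must lie in [0, 1]")
    unc = UncertaintyVector.uniform(label_set, 100.0 * error_rate)
    return Expert(
        expert_id=expert_id,
        kind="perfect",
        base_cost=unit_cost,
        uncertainty=unc,
        unit_cost=float(unit_cost),
        updatable=False,
        label_set=tuple(label_set),
        error_rate=float(error_rate),
        _truth=truth_source,
        _rng=substream(seed, f"expert/{expert_id}"),
    )


def make_imperfect_expert(
    init_pool: Dictionary,
    data_fraction: float,
    eval_pool: Dictionary,
    base_cost: float,
    seed: int = 0,
    expert_id: str = "imperfect",
) -> Expert:
    """Partially knowledgeable annotator trained on a stratified
    ``data_fraction`` sample of the expert-initialization pool."""
    if not (0.0 < data_fraction <= 1.0):
        raise ConfigurationError("data_fraction must lie in (0, 1]")
    if data_fraction == 1.0:
        sample = init_pool
    else:
        sample, _ = split_expert_initialization(init_pool, data_fraction, seed=substream_seed(seed, f"{expert_id}/sample"))
    label_set = tuple(sorted(set(init_pool.labels_present()) | set(eval_pool.labels_present())))
    exp = Expert(
        expert_id=expert_id,
        kind="imperfect",
        base_cost=float(base_cost),
        uncertainty=UncertaintyVector.uniform(label_set, 100.0),
        unit_cost=0.0,
        updatable=True,
        label_set=label_set,
        _train=list(sample),
        _model_seed=substream_seed(seed, f"{expert_id}/model"),
    )
    exp._retrain()
    exp.uncertainty = _per_label_error(exp.raw_predict, eval_pool, label_set, {i.label for i in exp._train})
    exp.unit_cost = expert_cost_from_confidence(exp.uncertainty, exp.base_cost)
    return exp


def make_on_demand_expert(
    init_pool: Dictionary,
    confident_labels: Iterable[str],
    eval_pool: Dictionary,
    n_other: int = 3,
    base_cost: float = 0.0,
    seed: int = 0,
    expert_id: str = "on_demand",
) -> Expert:
    """Free (or nearly free) annotator confident on a label subset.

    Trained on all initialization data for its confident labels plus
    ``n_other`` instances per other label; abstains whenever its predicted
    label falls outside the confident set.
    """
    confident = frozenset(confident_labels)
    all_labels = set(init_pool.labels_present()) | set(eval_pool.labels_present())
    if not confident or not confident <= all_labels:
        raise ConfigurationError("confident_labels must be a non-empty subset of the label set")
    rng = substream(seed, f"expert/{expert_id}/select")
    train: list[FeatureInstance] = [i for i in init_pool if i.label in confident]
    for lab in sorted(all_labels - confident):
        cand = [i for i in init_pool if i.label == lab]
        if cand:
            pick = rng.choice(len(cand), size=min(n_other, len(cand)), replace=False)
            train.extend(cand[int(j)] for j in sorted(pick))
    label_set = tuple(sorted(all_labels))
    exp = Expert(
        expert_id=expert_id,
        kind="on_demand",
        base_cost=float(base_cost),
        uncertainty=UncertaintyVector.uniform(label_set, 100.0),
        unit_cost=0.0,
        updatable=True,
        label_set=label_set,
        confident_labels=confident,
        _train=train,
        _model_seed=substream_seed(seed, f"{expert_id}/model"),
    )
    exp._retrain()
    exp.uncertainty = _per_label_error(exp.raw_predict, eval_pool, label_set, {i.label for i in exp._train})
    exp.unit_cost = expert_cost_from_confidence(exp.uncertainty, exp.base_cost)
    return exp


def broadcast_labeled_data(batch: Iterable[FeatureInstance], pool: ExpertPool) -> ExpertPool:
    """Convey newly labeled instances to every updatable expert and retrain
    it; the perfect expert is left untouched."""
    batch = [b for b in batch if b.label is not None]
    if not batch:
        return pool
    for e in pool:
        if e.updatable:
            e._train.extend(batch)
            e._retrain()
    return pool


def update_uncertainty_all(pool: ExpertPool, eval_pool: Dictionary) -> ExpertPool:
    """Recompute every updatable expert's uncertainty score vector from its
    per-label error on the evaluation pool, then re-derive its query cost."""
    for e in pool:
        if not e.updatable:
            continue
        e.uncertainty = _per_label_error(
            e.raw_predict, eval_pool, e.label_set, {i.label for i in e._train}
        )
        e.unit_cost = expert_cost_from_confidence(e.uncertainty, e.base_cost)
    return pool
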