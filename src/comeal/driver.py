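"""Collaborative active-learning driver, baselines, and change scenarios.

The driver implements the full loop: transfer-learning initialization of the
learner from related source domains, optional auto-labeling from prior
knowledge, and rounds of querying in which the K most informative unlabeled
instances are annotated by the cheapest sufficiently confident experts,
newly labeled data is broadcast to updatable experts (collaboration), and
the learner is retrained.  The loop stops when the learner's per-label
uncertainty falls below the threshold everywhere, or when the query budget
(a fraction of the initial unlabeled pool) is spent.

Variants:

* **CAL** — collaborative active learning: transfer init + collaboration;
* **CAL\\*** — CAL plus the prior-knowledge path: instances the initial
  model labels confidently are moved to the labeled pool without queries;
* **NCAL** — CAL without the collaboration step (experts never learn);
* **RAL** — random query selection instead of informativeness (baseline);
* **STL** — no experts at all: each round adds the next most similar batch
  of *source* data, a pure transfer-learning baseline.

Three reconfiguration scenarios generate the study worlds: **context
change** (a new subject, leave-one-subject-out), **configuration change**
(a new sensor location with prior knowledge over a label subset), and
**user-need change** (new activity classes absent from every source domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._rng import substream, substream_seed
from .data import Dictionary, FeatureInstance, UncertaintyVector
from .emu import CostLedger, annotate
from .experts import (
    ExpertPool,
    broadcast_labeled_data,
    make_imperfect_expert,
    make_on_demand_expert,
    make_perfect_expert,
    update_uncertainty_all,
)
from .learner import RandomForestLearner, get_informative_instances, learner_uncertainty
from .synthgen import ConfigurationError, WorldConfig, generate_feature_world, split_expert_initialization
from .transfer import TransferReport, apply_prior_knowledge, initialize_learner

__all__ = [
    "RunConfig",
    "RoundTrace",
    "RunResult",
    "PoolSpec",
    "ScenarioData",
    "build_scenario",
    "run_driver",
    "run_stl_baseline",
    "VARIANTS",
    "SCENARIOS",
]

VARIANTS = ("CAL", "CAL_star", "NCAL", "RAL", "STL")
SCENARIOS = ("context_change", "configuration_change", "user_need_change")


@dataclass(frozen=True)
class RunConfig:
    """Active-learning run parameters.

    ``u_th`` is the target uncertainty threshold, given either as a fraction
    in (0, 1] (0.2 means 20 percentage points, broadcast over labels) or as
    a full per-label vector on the [0, 100] scale.  ``budget_fraction``
    bounds the number of queries by a fraction of the initial unlabeled
    pool, so runs terminate even when the threshold is unreachable.
    """

    K: int = 10
    u_th: float | dict | UncertaintyVector = 0.2
    variant: str = "CAL"
    strategy: str = "hybrid"
    budget_fraction: float = 0.15
    confidence_floor: float = 0.9
    n_estimators: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if not (0.0 < self.budget_fraction <= 1.0):
            raise ConfigurationError("budget_fraction must lie in (0, 1]")
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")


@dataclass
class RoundTrace:
    round_index: int
    n_labeled: int
    n_unlabeled: int
    accuracy: float
    uncertainty: UncertaintyVector
    queried_uids: list[int] = field(default_factory=list)


@dataclass
class RunResult:
    variant: str
    model: Optional[RandomForestLearner]
    ledger: CostLedger
    rounds: list[RoundTrace]
    transfer_report: Optional[TransferReport] = None

    @property
    def final_accuracy(self) -> float:
        return self.rounds[-1].accuracy if self.rounds else float("nan")

    def accuracy_trace(self) -> list[float]:
        return [r.accuracy for r in self.rounds]

    def queries_of_kind(self, kind: str) -> int:
        return sum(self.ledger.query_counts(kind).values())


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolSpec:
    """Layout of the simulated expert pool.

    One near-perfect annotator (error probability in the 1–10% band, most
    expensive), a set of imperfect annotators trained on small stratified
    fractions of the expert-initialization data, and a set of free on-demand
    annotators each confident on roughly a quarter of the label set.
    """

    perfect_error: float = 0.05
    perfect_cost: float = 10.0
    imperfect_fractions: tuple[float, ...] = (0.05, 0.05)
    imperfect_costs: tuple[float, ...] = (5.0, 4.0)
    n_on_demand: int = 2
    on_demand_cost: float = 0.0
    n_other: int = 3


@dataclass
class ScenarioData:
    """Everything a run needs: source domains, pools, experts, hidden truth."""

    scenario: str
    related: list[Dictionary]
    X_L: Dictionary
    X_U: Dictionary
    hidden_truth: dict[int, str]
    eval_pool: Dictionary
    pool: ExpertPool
    label_set: tuple[str, ...]
    expert_init: Dictionary


def _strip_labels(pool: Dictionary) -> tuple[Dictionary, dict[int, str]]:
    truth: dict[int, str] = {}
    stripped = []
    for inst in pool:
        truth[inst.uid] = inst.label
        stripped.append(
            FeatureInstance(
                features=inst.features,
                label=None,
                subject_id=inst.subject_id,
                location_id=inst.location_id,
                window_index=inst.window_index,
                uid=inst.uid,
            )
        )
    return Dictionary(stripped, role="target_unlabeled", domain_id=pool.domain_id), truth


def _build_pool(
    expert_init: Dictionary,
    eval_pool: Dictionary,
    hidden_truth: dict[int, str],
    label_set: Sequence[str],
    spec: PoolSpec,
    seed: int,
) -> ExpertPool:
    def truth_fn(x: FeatureInstance) -> str:
        if x.uid in hidden_truth:
            return hidden_truth[x.uid]
        if x.label is not None:
            return x.label
        raise KeyError(f"no ground truth for instance uid={x.uid}")

    experts = [
        make_perfect_expert(
            truth_fn,
            error_rate=spec.perfect_error,
            unit_cost=spec.perfect_cost,
            label_set=label_set,
            seed=substream_seed(seed, "pool/perfect"),
            expert_id="E1_perfect",
        )
    ]
    for i, (frac, cost) in enumerate(zip(spec.imperfect_fractions, spec.imperfect_costs)):
        experts.append(
            make_imperfect_expert(
                expert_init,
                data_fraction=frac,
                eval_pool=eval_pool,
                base_cost=cost,
                seed=substream_seed(seed, f"pool/imperfect{i}"),
                expert_id=f"E{i + 2}_imperfect",
            )
        )
    k = len(label_set)
    n_conf = max(1, round(k / 4))
    base = 2 + len(spec.imperfect_fractions)
    for i in range(spec.n_on_demand):
        confident = tuple(label_set[(i * n_conf + j) % k] for j in range(n_conf))
        experts.append(
            make_on_demand_expert(
                expert_init,
                confident_labels=confident,
                eval_pool=eval_pool,
                n_other=spec.n_other,
                base_cost=spec.on_demand_cost,
                seed=substream_seed(seed, f"pool/ondemand{i}"),
                expert_id=f"E{base + i}_ondemand",
            )
        )
    return ExpertPool(experts=experts, label_set=tuple(label_set))


def build_scenario(
    scenario: str,
    world_cfg: WorldConfig,
    seed: int = 0,
    pool_spec: PoolSpec = PoolSpec(),
    q: int = 8,
    n_per_class: int = 150,
    n_new_labels: int = 2,
    prior_per_label: int = 10,
) -> ScenarioData:
    """Instantiate one reconfiguration scenario on a synthetic feature world.

    The target domain's data is split 50/50 into an expert-initialization
    pool (training simulated experts) and a remainder; the remainder splits
    60/40 into the unlabeled query pool X_U (hidden truth kept aside) and a
    held-out evaluation pool used both for accuracy reporting and for expert
    uncertainty estimation.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    cfg = world_cfg
    world = generate_feature_world(cfg, q=q, n_per_class=n_per_class)
    subjects, locations = cfg.subjects(), cfg.locations()
    label_set = tuple(cfg.label_set)

    if scenario == "context_change":
        if cfg.n_subjects < 2:
            raise ConfigurationError("context change needs >= 2 subjects")
        target_subj, loc = subjects[-1], locations[0]
        related = [world[(s, loc)].copy() for s in subjects[:-1]]
        target_table = world[(target_subj, loc)]
        new_labels: tuple[str, ...] = ()
    elif scenario == "configuration_change":
        if cfg.n_locations < 2:
            raise ConfigurationError("configuration change needs >= 2 locations")
        target_subj, loc = subjects[-1], locations[-1]
        related = [world[(target_subj, l)].copy() for l in locations[:-1]]
        related += [world[(s, loc)].copy() for s in subjects[:-1]]
        target_table = world[(target_subj, loc)]
        new_labels = ()
    else:  # user_need_change
        if len(label_set) < n_new_labels + 2:
            raise ConfigurationError("user-need change needs >= 2 spare labels")
        target_subj, loc = subjects[-1], locations[0]
        new_labels = label_set[-n_new_labels:]
        related = []
        for s in subjects[:-1]:
            src = world[(s, loc)]
            kept = [i for i in src if i.label not in new_labels]
            related.append(Dictionary(kept, role="related_labeled", domain_id=src.domain_id))
        target_table = world[(target_subj, loc)]

    expert_init, remainder = split_expert_initialization(
        target_table, 0.5, seed=substream_seed(seed, "scenario/init-split")
    )
    xu_labeled, eval_pool = split_expert_initialization(
        remainder, 0.6, seed=substream_seed(seed, "scenario/eval-split")
    )
    eval_pool = eval_pool.copy(role="related_labeled")
    X_U, hidden_truth = _strip_labels(xu_labeled)

    if scenario == "configuration_change":
        covered = label_set[: math.ceil(len(label_set) / 2)]
        prior = []
        for lab in covered:
            prior.extend([i for i in expert_init if i.label == lab][:prior_per_label])
        X_L = Dictionary(prior, role="target_labeled", domain_id="prior")
    else:
        X_L = Dictionary([], role="target_labeled", domain_id="target")

    pool = _build_pool(expert_init, eval_pool, hidden_truth, label_set, pool_spec, seed)
    return ScenarioData(
        scenario=scenario,
        related=related,
        X_L=X_L,
        X_U=X_U,
        hidden_truth=hidden_truth,
        eval_pool=eval_pool,
        pool=pool,
        label_set=label_set,
        expert_init=expert_init,
    )


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _safe_accuracy(model: Optional[RandomForestLearner], eval_pool: Dictionary) -> float:
    if model is None or not model.is_trained or len(eval_pool) == 0:
        return float("nan")
    return model.accuracy(eval_pool)


def run_driver(
    related: Sequence[Dictionary],
    X_L: Dictionary,
    X_U: Dictionary,
    label_set: Sequence[str],
    pool: ExpertPool,
    cfg: RunConfig,
    eval_pool: Dictionary,
) -> RunResult:
    """Execute the collaborative active-learning loop (variants CAL, CAL*,
    NCAL, RAL); see the module docstring.  Mutates neither input pool:
    labeled/unlabeled pools are copied before the loop."""
    if len(pool) == 0:
        raise ConfigurationError("expert pool is empty")
    if cfg.variant == "STL":
        return run_stl_baseline(related, X_L, X_U, label_set, cfg, eval_pool)

    labels = tuple(label_set)
    u_th = UncertaintyVector.from_scalar_or_mapping(cfg.u_th, labels)
    X_L = X_L.copy()
    X_U = X_U.copy()
    n_initial_unlabeled = len(X_U)
    budget = max(1, math.ceil(cfg.budget_fraction * n_initial_unlabeled))
    query_rng = substream(cfg.seed, "driver/query")
    conserved = len(X_L) + len(X_U)

    report: Optional[TransferReport] = None
    if related:
        db_l, report = initialize_learner(related, X_U, labels, seed=cfg.seed)
        X_L.extend(db_l)
        conserved += len(db_l)

    model = RandomForestLearner(n_estimators=cfg.n_estimators, seed=substream_seed(cfg.seed, "driver/forest"))
    if len(X_L) == 0:
        raise ConfigurationError("no labeled data after initialization")
    model.fit(X_L)

    if cfg.variant == "CAL_star":
        auto, X_U = apply_prior_knowledge(model, X_U, cfg.confidence_floor)
        X_L.extend(auto)
        model.fit(X_L)

    ledger = CostLedger()
    rounds: list[RoundTrace] = [
        RoundTrace(
            round_index=0,
            n_labeled=len(X_L),
            n_unlabeled=len(X_U),
            accuracy=_safe_accuracy(model, eval_pool),
            uncertainty=learner_uncertainty(model, X_U, labels) if len(X_U) else UncertaintyVector.uniform(labels, 0.0),
        )
    ]
    total_queried = 0
    while total_queried < budget and len(X_U) > 0:
        u_vec = learner_uncertainty(model, X_U, labels)
        if u_vec.leq(u_th):
            break
        k_now = min(cfg.K, budget - total_queried, len(X_U))
        strategy = "random" if cfg.variant == "RAL" else cfg.strategy
        batch = get_informative_instances(k_now, X_U, model, strategy, rng=query_rng)
        ledger.begin_round()
        newly_labeled: list[FeatureInstance] = []
        for inst in batch:
            semi = model.predict_label(inst)
            answer = annotate(inst, pool, semi, u_th, ledger)
            newly_labeled.append(inst.with_label(answer))
        X_U.remove_uids([i.uid for i in batch])
        X_L.extend(newly_labeled)
        if cfg.variant in ("CAL", "CAL_star", "RAL"):
            broadcast_labeled_data(newly_labeled, pool)
            update_uncertainty_all(pool, eval_pool)
        model.fit(X_L)
        total_queried += len(batch)
        assert len(X_L) + len(X_U) == conserved, "pool conservation violated"
        rounds.append(
            RoundTrace(
                round_index=len(rounds),
                n_labeled=len(X_L),
                n_unlabeled=len(X_U),
                accuracy=_safe_accuracy(model, eval_pool),
                uncertainty=learner_uncertainty(model, X_U, labels) if len(X_U) else UncertaintyVector.uniform(labels, 0.0),
                queried_uids=[i.uid for i in batch],
            )
        )
    assert abs(ledger.total_cost - sum(r.cost for r in ledger.records)) < 1e-9
    return RunResult(variant=cfg.variant, model=model, ledger=ledger, rounds=rounds, transfer_report=report)


def run_stl_baseline(
    related: Sequence[Dictionary],
    X_L: Dictionary,
    X_U: Dictionary,
    label_set: Sequence[str],
    cfg: RunConfig,
    eval_pool: Dictionary,
) -> RunResult:
    """Simple transfer-learning baseline: no expert queries; each round adds
    the next most similar batch of source instances (by cosine similarity to
    the target cluster centres), retrains, and records accuracy."""
    if not related:
        raise ConfigurationError("STL needs at least one related domain")
    from sklearn.cluster import KMeans

    labels = tuple(label_set)
    X_L = X_L.copy()
    km = KMeans(
        n_clusters=len(labels), n_init=10,
        random_state=substream_seed(cfg.seed, "stl/kmeans"),
    ).fit(X_U.X)
    centers = km.cluster_centers_

    candidates: list[tuple[float, int, FeatureInstance]] = []
    order = 0
    for src in related:
        for inst in src:
            norm = np.linalg.norm(inst.features)
            if norm == 0:
                sim = -1.0
            else:
                sims = centers @ inst.features / (np.linalg.norm(centers, axis=1) * norm + 1e-300)
                sim = float(sims.max())
            candidates.append((sim, order, inst))
            order += 1
    candidates.sort(key=lambda t: (-t[0], t[1]))
    n_source = len(candidates)
    budget = max(1, math.ceil(cfg.budget_fraction * n_source))

    model = RandomForestLearner(n_estimators=cfg.n_estimators, seed=substream_seed(cfg.seed, "stl/forest"))
    rounds: list[RoundTrace] = []
    if len(X_L) > 0:
        model.fit(X_L)
    rounds.append(
        RoundTrace(
            round_index=0, n_labeled=len(X_L), n_unlabeled=len(X_U),
            accuracy=_safe_accuracy(model, eval_pool),
            uncertainty=UncertaintyVector.uniform(labels, 100.0),
        )
    )
    added = 0
    while added < budget and added < n_source:
        batch = [inst for _, _, inst in candidates[added : min(added + cfg.K, budget, n_source)]]
        if not batch:
            break
        X_L.extend(batch)
        added += len(batch)
        model.fit(X_L)
        rounds.append(
            RoundTrace(
                round_index=len(rounds), n_labeled=len(X_L), n_unlabeled=len(X_U),
                accuracy=_safe_accuracy(model, eval_pool),
                uncertainty=learner_uncertainty(model, X_U, labels) if len(X_U) else UncertaintyVector.uniform(labels, 0.0),
            )
        )
    return RunResult(variant="STL", model=model, ledger=CostLedger(), rounds=rounds)
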