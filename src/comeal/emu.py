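"""Expert management unit: cost-minimizing annotation and the exact oracle.

Choosing which expert answers which query is an integer linear program:
minimize Σᵢ Σⱼ βᵢ αᵢⱼ cᵢⱼ subject to each selected instance being asked from
exactly one expert whose uncertainty on the instance's semi-label is below
the threshold (βᵢ, αᵢⱼ binary).  Because the one-expert-per-instance
constraint decouples across instances and costs are additive, the exact
optimum on a *fixed* set of semi-labels is the sum of independent
per-instance minima — :func:`exact_assignment_oracle` computes it by
exhaustive enumeration of each instance's feasible experts and certifies the
greedy routine on small tables.

The online greedy, :func:`annotate`, works in two phases per query:

1. ask every on-demand expert (little or zero cost); if their non-abstaining
   answers have a majority label, it becomes the semi-label and the running
   uncertainty ``u`` becomes the minimum uncertainty on that label among the
   agreeing on-demand experts;
2. while ``u`` exceeds the per-label threshold, ask the cheapest
   perfect/imperfect expert that is confident enough on the current
   semi-label; its answer may revise the semi-label, in which case the loop
   re-evaluates.  A cap of |pool| iterations prevents cycling, after which
   the perfect expert is forced.

Every charge is appended to a :class:`CostLedger`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .data import FeatureInstance, UncertaintyVector
from .experts import Expert, ExpertPool

__all__ = [
    "CostLedger",
    "AssignmentSolution",
    "majority_vote",
    "annotate",
    "exact_assignment_oracle",
    "enumerate_joint_assignments",
    "EscalationError",
]

#: sentinel uncertainty before any expert has answered
_U_INIT = 100.0


class EscalationError(RuntimeError):
    """No expert in the pool is confident enough for the blocking label."""

    def __init__(self, label: str) -> None:
        super().__init__(f"no expert satisfies the uncertainty threshold for label {label!r}")
        self.label = label


@dataclass
class LedgerRecord:
    round_index: int
    instance_uid: Optional[int]
    expert_id: str
    expert_kind: str
    cost: float
    returned_label: Optional[str]
    semi_label_at_ask: str


@dataclass
class CostLedger:
    """Append-only record of every expert charge, grouped by query round."""

    records: list[LedgerRecord] = field(default_factory=list)
    _round: int = 0

    def begin_round(self) -> int:
        self._round += 1
        return self._round

    def charge(
        self,
        instance: FeatureInstance,
        expert: Expert,
        returned_label: Optional[str],
        semi_label: str,
    ) -> None:
        self.records.append(
            LedgerRecord(
                round_index=self._round,
                instance_uid=instance.uid,
                expert_id=expert.expert_id,
                expert_kind=expert.kind,
                cost=float(expert.unit_cost),
                returned_label=returned_label,
                semi_label_at_ask=semi_label,
            )
        )

    @property
    def total_cost(self) -> float:
        return float(sum(r.cost for r in self.records))

    def query_counts(self, kind: Optional[str] = None) -> dict[str, int]:
        """Number of queries per expert id, optionally restricted to a kind."""
        counts: dict[str, int] = {}
        for r in self.records:
            if kind is not None and r.expert_kind != kind:
                continue
            counts[r.expert_id] = counts.get(r.expert_id, 0) + 1
        return counts

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(vars(r)) for r in self.records)

    def summary_frame(self) -> pd.DataFrame:
        """Per-expert query counts and cost totals (the data behind
        cost-evaluation plots)."""
        rows: dict[str, dict] = {}
        for r in self.records:
            row = rows.setdefault(
                r.expert_id, {"expert_id": r.expert_id, "kind": r.expert_kind, "queries": 0, "cost": 0.0}
            )
            row["queries"] += 1
            row["cost"] += r.cost
        return pd.DataFrame(sorted(rows.values(), key=lambda d: d["expert_id"]))


def majority_vote(answers: Sequence[tuple[str, str]]) -> Optional[str]:
    """Modal label among (expert id, label) answers; ties and empty input
    yield ``None``."""
    counts: dict[str, int] = {}
    for _, lab in answers:
        counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else None


def annotate(
    x: FeatureInstance,
    pool: ExpertPool,
    semi_label: str,
    u_th: UncertaintyVector,
    ledger: CostLedger,
) -> str:
    """Obtain a label for ``x`` from the cheapest sufficiently confident
    expert; see the module docstring for the two-phase procedure.

    ``semi_label`` is the learner's current most probable label for ``x``;
    it may be revised first by the on-demand majority vote and then by
    phase-2 answers.  Raises :class:`EscalationError` when no expert is
    confident enough for the current semi-label.
    """
    u = _U_INIT
    # Phase 1: query all on-demand experts unconditionally (they are free or
    # nearly free); abstentions return None and do not vote.
    answers: list[tuple[str, str]] = []
    voters: dict[str, list[Expert]] = {}
    for e in pool.of_kind("on_demand"):
        ans = e.query(x)
        ledger.charge(x, e, ans, semi_label)
        if ans is not None:
            answers.append((e.expert_id, ans))
            voters.setdefault(ans, []).append(e)
    maj = majority_vote(answers)
    if maj is not None:
        semi_label = maj
        u = min(e.uncertainty.get(maj) for e in voters[maj])

    # Phase 2: escalate to perfect/imperfect experts until confident enough.
    max_iters = max(1, len(pool))
    iters = 0
    while u > u_th.get(semi_label):
        iters += 1
        if iters > max_iters:
            # cycling between semi-labels: force the (cheapest) perfect expert
            perfect = pool.of_kind("perfect")
            if not perfect:
                raise EscalationError(semi_label)
            e = min(perfect, key=lambda e: e.unit_cost)
            ans = e.query(x)
            ledger.charge(x, e, ans, semi_label)
            return ans
        cands = [
            e
            for e in pool.of_kind("perfect", "imperfect")
            if e.uncertainty.get(semi_label) <= u_th.get(semi_label)
        ]
        if not cands:
            raise EscalationError(semi_label)
        e = min(cands, key=lambda e: e.unit_cost)  # stable: pool order breaks ties
        ans = e.query(x)
        ledger.charge(x, e, ans, semi_label)
        if ans is None:  # degenerate: untrained expert admitted by a vacuous threshold
            continue
        semi_label = ans
        u = e.uncertainty.get(ans)
    return semi_label


@dataclass
class AssignmentSolution:
    """Optimal instance→expert assignment for fixed semi-labels.

    ``assignment`` maps each feasible instance's uid to the chosen expert id;
    ``infeasible`` lists (uid, semi_label) pairs with no confident expert.
    """

    assignment: dict[int, str]
    total_cost: float
    infeasible: list[tuple[int, str]]


def _feasible(e: Expert, semi_label: str, u_th: UncertaintyVector) -> bool:
    return e.uncertainty.get(semi_label) <= u_th.get(semi_label)


def exact_assignment_oracle(
    items: Sequence[tuple[int, str]],
    pool: ExpertPool,
    u_th: UncertaintyVector,
) -> AssignmentSolution:
    """Exact minimum-cost assignment for ≤ 12 instances × ≤ 8 experts.

    Enumerates each instance's feasible expert set exhaustively; the
    one-expert-per-instance constraint makes the joint optimum the sum of
    per-instance minima, which :func:`enumerate_joint_assignments` verifies
    by brute force in tests.
    """
    if len(items) > 12 or len(pool) > 8:
        raise ValueError("oracle is limited to 12 instances x 8 experts")
    assignment: dict[int, str] = {}
    infeasible: list[tuple[int, str]] = []
    total = 0.0
    for uid, semi in items:
        feas = [e for e in pool if _feasible(e, semi, u_th)]
        if not feas:
            infeasible.append((uid, semi))
            continue
        best = min(feas, key=lambda e: e.unit_cost)
        assignment[uid] = best.expert_id
        total += best.unit_cost
    return AssignmentSolution(assignment=assignment, total_cost=float(total), infeasible=infeasible)


def enumerate_joint_assignments(
    items: Sequence[tuple[int, str]],
    pool: ExpertPool,
    u_th: UncertaintyVector,
) -> Optional[float]:
    """Brute-force minimum total cost over the full joint assignment space
    (test oracle; exponential).  Returns ``None`` if any instance has no
    feasible expert."""
    feasible_sets = []
    for _, semi in items:
        feas = [e for e in pool if _feasible(e, semi, u_th)]
        if not feas:
            return None
        feasible_sets.append(feas)
    best = np.inf
    for combo in product(*feasible_sets):
        best = min(best, sum(e.unit_cost for e in combo))
    return float(best) if np.isfinite(best) else None
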