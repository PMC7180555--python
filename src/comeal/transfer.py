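"""Transfer-learning initialization of the target learner.

When the system enters a new context (a new subject, sensor location, or
activity set), its unlabeled target pool X_U can be seeded with labeled data
from related source domains.  The procedure:

1. k-means clusters the target features with k = |label set|;
2. for every source domain, per-label class centres (feature means) are
   compared with the target cluster centres by cosine similarity;
3. clusters are assigned to labels by greedy maximum-weight one-to-one
   matching on the label × cluster similarity table (taking, per cell, the
   best source), so no two labels claim the same cluster;
4. for each label, the source domain whose class centre is most similar to
   its matched cluster centre contributes its instances for that label —
   different labels may draw from different sources.

The union of the selected per-label subsets is the transfer-output pool
DB_L used to fit the initial model.  When a previously trained model's
knowledge still applies (a configuration upgrade rather than a distribution
change), :func:`apply_prior_knowledge` auto-labels the target instances the
model is confident about instead of spending queries on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._rng import substream_seed
from .data import Dictionary, FeatureInstance, InputError
from .learner import RandomForestLearner

__all__ = [
    "cosine_similarity",
    "initialize_learner",
    "apply_prior_knowledge",
    "TransferReport",
    "InitializationError",
]


class InitializationError(ValueError):
    pass


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a·b / (‖a‖ ‖b‖), in [−1, 1]; zero vectors are rejected."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("vectors must be 1-D and of equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise InputError("cosine similarity undefined for zero vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class TransferReport:
    """Chosen source and similarity per label (the transfer audit trail)."""

    rows: pd.DataFrame  # columns: label, cluster, source, similarity

    def source_for(self, label: str) -> Optional[str]:
        hit = self.rows[self.rows["label"] == label]
        if hit.empty or pd.isna(hit.iloc[0]["source"]):
            return None
        return str(hit.iloc[0]["source"])


def _class_centers(pool: Dictionary) -> dict[str, np.ndarray]:
    centers: dict[str, np.ndarray] = {}
    for lab in pool.labels_present():
        X = np.vstack([i.features for i in pool if i.label == lab])
        centers[lab] = X.mean(axis=0)
    return centers


def _greedy_matching(sim: np.ndarray) -> dict[int, int]:
    """Greedy maximum-weight one-to-one matching row→column on ``sim``
    (−inf marks forbidden cells); remaining rows get leftover columns in
    index order."""
    n_rows, n_cols = sim.shape
    match: dict[int, int] = {}
    used_cols: set[int] = set()
    work = sim.copy()
    while len(match) < min(n_rows, n_cols):
        flat = np.argmax(work)
        r, c = divmod(int(flat), n_cols)
        if not np.isfinite(work[r, c]):
            break  # only forbidden cells left
        match[r] = c
        used_cols.add(c)
        work[r, :] = -np.inf
        work[:, c] = -np.inf
    leftover_cols = [c for c in range(n_cols) if c not in used_cols]
    for r in range(n_rows):
        if r not in match and leftover_cols:
            match[r] = leftover_cols.pop(0)
    return match


def initialize_learner(
    related: Sequence[Dictionary],
    target_unlabeled: Dictionary,
    label_set: Sequence[str],
    seed: int = 0,
) -> tuple[Dictionary, TransferReport]:
    """Assemble the transfer-output pool DB_L from the most similar sources.

    Labels for which no source domain has any data (e.g. genuinely new
    activities) contribute nothing to DB_L and appear in the report with a
    missing source.
    """
    labels = list(label_set)
    k = len(labels)
    if len(target_unlabeled) < k:
        raise InitializationError("need at least k target instances to cluster")
    X = target_unlabeled.X
    if len(np.unique(X, axis=0)) < k:
        raise InitializationError("fewer distinct target points than clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=substream_seed(seed, "transfer/kmeans"))
    km.fit(X)
    cluster_centers = km.cluster_centers_

    source_centers = [( d, _class_centers(d)) for d in related]
    # label × cluster best-over-sources similarity, plus the argmax source
    sim = np.full((k, k), -np.inf)
    best_source = np.full((k, k), -1, dtype=int)
    for li, lab in enumerate(labels):
        for ci in range(k):
            for si, (_, centers) in enumerate(source_centers):
                if lab not in centers:
                    continue
                s = cosine_similarity(centers[lab], cluster_centers[ci])
                if s > sim[li, ci]:
                    sim[li, ci] = s
                    best_source[li, ci] = si

    match = _greedy_matching(sim)
    out: list[FeatureInstance] = []
    rows = []
    for li, lab in enumerate(labels):
        ci = match.get(li)
        si = best_source[li, ci] if ci is not None else -1
        if ci is None or si < 0:
            rows.append({"label": lab, "cluster": ci, "source": np.nan, "similarity": np.nan})
            continue
        src = source_centers[si][0]
        out.extend(i for i in src if i.label == lab)
        rows.append(
            {
                "label": lab,
                "cluster": ci,
                "source": src.domain_id if src.domain_id is not None else str(si),
                "similarity": float(sim[li, ci]),
            }
        )
    db_l = Dictionary(out, role="transfer_output", domain_id="transfer")
    return db_l, TransferReport(rows=pd.DataFrame(rows))


def apply_prior_knowledge(
    model: RandomForestLearner,
    target_unlabeled: Dictionary,
    confidence_floor: float = 0.9,
) -> tuple[Dictionary, Dictionary]:
    """Auto-label the target instances the prior model is confident about.

    Instances whose max posterior reaches ``confidence_floor`` move to the
    labeled side carrying the model's predicted label; the rest stay
    unlabeled.  Returns ``(auto_labeled, remaining_unlabeled)``.
    """
    if not model.is_trained:
        raise InitializationError("prior model must be trained")
    if len(target_unlabeled) == 0:
        return (
            Dictionary([], role="target_labeled"),
            Dictionary([], role="target_unlabeled"),
        )
    post = model.predict_posterior(target_unlabeled.X)
    conf = post.max(axis=1)
    pred = post.argmax(axis=1)
    auto, rest = [], []
    for i, inst in enumerate(target_unlabeled):
        if conf[i] >= confidence_floor:
            auto.append(inst.with_label(model.label_space[int(pred[i])]))
        else:
            rest.append(inst)
    return (
        Dictionary(auto, role="target_labeled", domain_id=target_unlabeled.domain_id),
        Dictionary(rest, role="target_unlabeled", domain_id=target_unlabeled.domain_id),
    )
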