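"""Core in-memory containers: feature instances, dictionaries, uncertainty vectors.

A *dictionary* is an unordered pool of windowed feature instances playing one
of three roles in the active-learning loop: the target-context unlabeled pool
(``target_unlabeled``), the target labeled pool (``target_labeled``), or one
related labeled source domain (``related_labeled``).  A fourth role,
``transfer_output``, marks the pool assembled by transfer-learning
initialization.

An *uncertainty score vector* attaches to any knowledge source (an expert or
the learner itself) and stores, per label, an uncertainty percentage in
[0, 100]; 0 means full confidence on that label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureInstance", "Dictionary", "UncertaintyVector", "DictionaryRole"]

DictionaryRole = str
_ROLES = ("target_unlabeled", "target_labeled", "related_labeled", "transfer_output")


class InputError(ValueError):
    """Raised for malformed numeric inputs."""


@dataclass
class FeatureInstance:
    """One segmented window as a q-dimensional feature vector.

    ``label`` is ``None`` for unlabeled instances; the hidden ground truth of
    an unlabeled pool is kept outside the instance (see the scenario builder)
    so no code path can accidentally peek at it.
    """

    features: np.ndarray
    label: Optional[str] = None
    subject_id: Optional[str] = None
    location_id: Optional[str] = None
    window_index: Optional[int] = None
    uid: Optional[int] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise InputError("feature vector must be 1-D")
        if not np.all(np.isfinite(self.features)):
            raise InputError("feature values must be finite")

    def with_label(self, label: str) -> "FeatureInstance":
        return replace(self, label=label)


class Dictionary:
    """An unordered pool of :class:`FeatureInstance` with a database role.

    Insertion order is retained only as a deterministic tie-break for query
    strategies; no algorithm may rely on it semantically.
    """

    def __init__(
        self,
        instances: Iterable[FeatureInstance] = (),
        role: DictionaryRole = "related_labeled",
        domain_id: Optional[str] = None,
    ) -> None:
        if role not in _ROLES:
            raise ValueError(f"unknown dictionary role {role!r}")
        self.role = role
        self.domain_id = domain_id
        self._instances: list[FeatureInstance] = list(instances)
        self._check_labels()

    def _check_labels(self) -> None:
        if self.role in ("related_labeled", "target_labeled", "transfer_output"):
            if any(inst.label is None for inst in self._instances):
                raise ValueError(f"all instances in a {self.role} dictionary must be labeled")
        elif self.role == "target_unlabeled":
            if any(inst.label is not None for inst in self._instances):
                raise ValueError("target_unlabeled instances must not carry labels")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._instances)

    def __iter__(self) -> Iterator[FeatureInstance]:
        return iter(self._instances)

    def __getitem__(self, i: int) -> FeatureInstance:
        return self._instances[i]

    @property
    def instances(self) -> Sequence[FeatureInstance]:
        return tuple(self._instances)

    def add(self, inst: FeatureInstance) -> None:
        self._instances.append(inst)

    def extend(self, insts: Iterable[FeatureInstance]) -> None:
        self._instances.extend(insts)

    def remove_uids(self, uids: Iterable[int]) -> list[FeatureInstance]:
        """Remove and return all instances whose ``uid`` is in ``uids``."""
        wanted = set(uids)
        removed = [i for i in self._instances if i.uid in wanted]
        self._instances = [i for i in self._instances if i.uid not in wanted]
        return removed

    def copy(self, role: Optional[DictionaryRole] = None) -> "Dictionary":
        return Dictionary(list(self._instances), role=role or self.role, domain_id=self.domain_id)

    # -- array views --------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        """(n, q) feature matrix."""
        if not self._instances:
            return np.empty((0, 0))
        return np.vstack([inst.features for inst in self._instances])

    @property
    def y(self) -> list[Optional[str]]:
        return [inst.label for inst in self._instances]

    def labels_present(self) -> list[str]:
        return sorted({inst.label for inst in self._instances if inst.label is not None})

    # -- tabular round-trip --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Feature-table form with columns ``f1..fq,label,subject,location``."""
        X = self.X
        q = X.shape[1]
        df = pd.DataFrame(X, columns=[f"f{i + 1}" for i in range(q)])
        df["label"] = [i.label if i.label is not None else "" for i in self._instances]
        df["subject"] = [i.subject_id or "" for i in self._instances]
        df["location"] = [i.location_id or "" for i in self._instances]
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        role: DictionaryRole = "related_labeled",
        domain_id: Optional[str] = None,
    ) -> "Dictionary":
        feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        feat_cols.sort(key=lambda c: int(c[1:]))
        insts = []
        for idx, row in enumerate(df.itertuples(index=False)):
            d = row._asdict()
            label = d.get("label")
            label = None if label in ("", None) or (isinstance(label, float) and np.isnan(label)) else str(label)
            insts.append(
                FeatureInstance(
                    features=np.array([d[c] for c in feat_cols], dtype=float),
                    label=label,
                    subject_id=str(d["subject"]) if d.get("subject") not in ("", None) else None,
                    location_id=str(d["location"]) if d.get("location") not in ("", None) else None,
                    window_index=idx,
                )
            )
        return cls(insts, role=role, domain_id=domain_id)


@dataclass
class UncertaintyVector:
    """Per-label uncertainty percentages in [0, 100]."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, u in self.values.items():
            if not (0.0 <= u <= 100.0):
                raise InputError(f"uncertainty for {label!r} outside [0, 100]: {u}")

    @classmethod
    def uniform(cls, labels: Iterable[str], value: float) -> "UncertaintyVector":
        return cls({lab: float(value) for lab in labels})

    @classmethod
    def from_scalar_or_mapping(
        cls, u_th: "float | Mapping[str, float] | UncertaintyVector", labels: Iterable[str]
    ) -> "UncertaintyVector":
        """Broadcast a scalar threshold over ``labels``; fractions in (0, 1] are
        interpreted on the percentage scale (0.2 -> 20)."""
        if isinstance(u_th, UncertaintyVector):
            return u_th
        if isinstance(u_th, Mapping):
            return cls(dict(u_th))
        v = float(u_th)
        if 0.0 < v <= 1.0:
            v *= 100.0
        return cls.uniform(labels, v)

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def get(self, label: str, default: float = 100.0) -> float:
        return self.values.get(label, default)

    def labels(self) -> list[str]:
        return sorted(self.values)

    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    def leq(self, other: "UncertaintyVector") -> bool:
        """Elementwise ``self <= other`` over this vector's label domain."""
        return all(self.values[lab] <= other.get(lab) for lab in self.values)
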