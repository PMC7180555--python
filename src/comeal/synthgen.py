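"""Synthetic multi-subject, multi-location sensor worlds.

Real multi-subject wearable datasets exhibit (i) quasi-periodic per-activity
waveforms, (ii) inter-subject variation in speed and amplitude of the same
activity, and (iii) per-location differences in how an activity projects onto
the sensor channels.  The generator reproduces exactly this structure:

* each (activity, location) pair gets a base waveform — a sum of two to three
  sinusoids with activity-specific frequencies and amplitudes plus a DC
  offset, drawn once per world;
* each subject applies an affine distortion to every base waveform (a random
  gain in ``[1 - s, 1 + s]`` and an offset ~ N(0, s), with
  ``s = subject_shift_scale``), modelling inter-subject context change;
* white Gaussian noise scaled by ``noise_scale`` is added per sample.

A feature-space shortcut, :func:`generate_feature_world`, emits per-class
Gaussian clusters with the same subject-level affine shift so that learner
and expert-management code can be exercised without the signal pipeline.

All randomness flows from ``WorldConfig.seed`` through named substreams, so
two calls with the same configuration are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._rng import substream
from .data import Dictionary, FeatureInstance

__all__ = [
    "WorldConfig",
    "SensorStream",
    "generate_world",
    "generate_feature_world",
    "split_expert_initialization",
    "write_stream_csv",
    "read_stream_csv",
    "write_feature_csv",
    "read_feature_csv",
]


class ConfigurationError(ValueError):
    """Raised when a world or run configuration is invalid."""


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic sensor world.

    ``subject_shift_scale`` controls inter-subject context change (0 = all
    subjects identical); ``noise_scale`` controls per-sample sensor noise.
    """

    n_subjects: int = 3
    n_locations: int = 2
    label_set: tuple[str, ...] = ("walk", "run", "sit", "climb")
    sampling_hz: float = 50.0
    seconds_per_activity: float = 10.0
    channels_per_location: int = 3
    subject_shift_scale: float = 0.4
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "label_set", tuple(self.label_set))
        if self.n_subjects < 1 or self.n_locations < 1 or self.channels_per_location < 1:
            raise ConfigurationError("subject/location/channel counts must be positive")
        if len(set(self.label_set)) != len(self.label_set):
            raise ConfigurationError("label_set contains duplicates")
        if len(self.label_set) < 2:
            raise ConfigurationError("need at least 2 labels")
        if self.sampling_hz <= 0 or self.seconds_per_activity <= 0:
            raise ConfigurationError("sampling_hz and seconds_per_activity must be positive")
        if self.subject_shift_scale < 0 or self.noise_scale < 0:
            raise ConfigurationError("scales must be nonnegative")

    @property
    def k(self) -> int:
        return len(self.label_set)

    def subjects(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_subjects)]

    def locations(self) -> list[str]:
        return [f"loc{i + 1}" for i in range(self.n_locations)]


@dataclass
class SensorStream:
    """A raw multi-channel recording for one (subject, location)."""

    subject_id: str
    location_id: str
    sampling_hz: float
    samples: np.ndarray  # (time, channels)
    labels: list[str]  # per-sample activity label

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (time, channels) matrix")
        if self.samples.shape[0] != len(self.labels):
            raise ValueError("samples row count must equal labels length")


def _base_waveforms(cfg: WorldConfig) -> dict[tuple[str, str], dict]:
    """Draw per-(label, location) waveform parameters once per world."""
    rng = substream(cfg.seed, "world/waveforms")
    params: dict[tuple[str, str], dict] = {}
    for label in cfg.label_set:
        for loc in cfg.locations():
            n_comp = int(rng.integers(2, 4))  # 2 or 3 sinusoids
            params[(label, loc)] = {
                "freqs": rng.uniform(0.5, 5.0, size=(n_comp, cfg.channels_per_location)),
                "amps": rng.uniform(0.5, 2.0, size=(n_comp, cfg.channels_per_location)),
                "phases": rng.uniform(0, 2 * np.pi, size=(n_comp, cfg.channels_per_location)),
                "dc": rng.normal(0.0, 1.0, size=cfg.channels_per_location),
            }
    return params


def _subject_affine(cfg: WorldConfig) -> dict[str, tuple[float, np.ndarray]]:
    rng = substream(cfg.seed, "world/subjects")
    s = cfg.subject_shift_scale
    out = {}
    for subj in cfg.subjects():
        gain = float(rng.uniform(1.0 - s, 1.0 + s))
        offset = rng.normal(0.0, s if s > 0 else 0.0, size=cfg.channels_per_location)
        out[subj] = (gain, offset)
    return out


def generate_world(cfg: WorldConfig) -> list[SensorStream]:
    """Generate one :class:`SensorStream` per (subject, location).

    Each stream concatenates one segment per activity label, in ``label_set``
    order; segment length is ``seconds_per_activity * sampling_hz`` samples.
    """
    waves = _base_waveforms(cfg)
    affines = _subject_affine(cfg)
    n_seg = int(round(cfg.seconds_per_activity * cfg.sampling_hz))
    t = np.arange(n_seg) / cfg.sampling_hz
    streams = []
    for subj in cfg.subjects():
        gain, offset = affines[subj]
        for loc in cfg.locations():
            noise_rng = substream(cfg.seed, f"world/noise/{subj}/{loc}")
            chunks, labels = [], []
            for label in cfg.label_set:
                p = waves[(label, loc)]
                seg = np.zeros((n_seg, cfg.channels_per_location))
                for c in range(cfg.channels_per_location):
                    for comp in range(p["freqs"].shape[0]):
                        seg[:, c] += p["amps"][comp, c] * np.sin(
                            2 * np.pi * p["freqs"][comp, c] * t + p["phases"][comp, c]
                        )
                    seg[:, c] += p["dc"][c]
                seg = gain * seg + offset
                if cfg.noise_scale > 0:
                    seg = seg + noise_rng.normal(0.0, cfg.noise_scale, size=seg.shape)
                chunks.append(seg)
                labels.extend([label] * n_seg)
            streams.append(
                SensorStream(
                    subject_id=subj,
                    location_id=loc,
                    sampling_hz=cfg.sampling_hz,
                    samples=np.vstack(chunks),
                    labels=labels,
                )
            )
    return streams


def generate_feature_world(
    cfg: WorldConfig,
    q: int,
    n_per_class: int = 60,
    class_separation: float = 1.2,
) -> dict[tuple[str, str], Dictionary]:
    """Per-(subject, location) labeled feature tables with per-class Gaussian
    clusters and subject-specific affine mean shifts.

    Class centres are drawn once per (label, location) from N(0,
    ``class_separation``² I_q); within-class spread is unit variance.  The
    subject affine (gain, offset) mirrors :func:`generate_world`, so the
    cross-subject distribution shift grows with ``subject_shift_scale``.
    """
    if q < 1:
        raise ConfigurationError("q must be >= 1")
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    mean_rng = substream(cfg.seed, "featworld/means")
    centers = {
        (label, loc): mean_rng.normal(0.0, class_separation, size=q)
        for label in cfg.label_set
        for loc in cfg.locations()
    }
    subj_rng = substream(cfg.seed, "featworld/subjects")
    s = cfg.subject_shift_scale
    affines = {
        subj: (float(subj_rng.uniform(1.0 - s, 1.0 + s)), subj_rng.normal(0.0, s if s > 0 else 0.0, size=q))
        for subj in cfg.subjects()
    }
    world: dict[tuple[str, str], Dictionary] = {}
    uid = 0
    for subj in cfg.subjects():
        gain, offset = affines[subj]
        for loc in cfg.locations():
            rng = substream(cfg.seed, f"featworld/data/{subj}/{loc}")
            insts = []
            for label in cfg.label_set:
                mu = gain * centers[(label, loc)] + offset
                pts = rng.normal(0.0, 1.0, size=(n_per_class, q)) * np.sqrt(1.0 + cfg.noise_scale**2) + mu
                for w, x in enumerate(pts):
                    insts.append(
                        FeatureInstance(
                            features=x, label=label, subject_id=subj,
                            location_id=loc, window_index=w, uid=uid,
                        )
                    )
                    uid += 1
            world[(subj, loc)] = Dictionary(insts, role="related_labeled", domain_id=f"{subj}/{loc}")
    return world


def split_expert_initialization(
    data: Union[Dictionary, pd.DataFrame],
    ratio: float,
    seed: int = 0,
) -> tuple:
    """Stratified split into (expert-initialization pool, evaluation pool).

    Per label, ``floor(ratio * n)`` instances go to the first pool; which
    instances is decided by a seeded shuffle.  The two pools are disjoint and
    jointly exhaustive.
    """
    if not (0.0 < ratio < 1.0):
        raise ConfigurationError("ratio must lie in (0, 1)")
    if isinstance(data, pd.DataFrame):
        d = Dictionary.from_frame(data)
        first, second = split_expert_initialization(d, ratio, seed)
        return first.to_frame(), second.to_frame()
    if len(data) == 0:
        raise ConfigurationError("cannot split an empty pool")
    rng = substream(seed, "split")
    by_label: dict[Optional[str], list[int]] = {}
    for i, inst in enumerate(data):
        by_label.setdefault(inst.label, []).append(i)
    first_idx: list[int] = []
    for label in sorted(by_label, key=str):
        idx = np.array(by_label[label])
        perm = rng.permutation(len(idx))
        n_first = int(np.floor(ratio * len(idx)))
        first_idx.extend(idx[perm[:n_first]].tolist())
    first_set = set(first_idx)
    first = Dictionary(
        [data[i] for i in sorted(first_set)], role=data.role, domain_id=data.domain_id
    )
    second = Dictionary(
        [data[i] for i in range(len(data)) if i not in first_set],
        role=data.role,
        domain_id=data.domain_id,
    )
    return first, second


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def write_stream_csv(stream: SensorStream, path: Union[str, Path]) -> None:
    """``timestamp,<ch1..chC>,label`` — one file per (subject, location)."""
    n, c = stream.samples.shape
    df = pd.DataFrame(stream.samples, columns=[f"ch{i + 1}" for i in range(c)])
    df.insert(0, "timestamp", np.arange(n) / stream.sampling_hz)
    df["label"] = stream.labels
    df.to_csv(path, index=False, float_format="%.17g")


def read_stream_csv(path: Union[str, Path], subject_id: str = "", location_id: str = "") -> SensorStream:
    df = pd.read_csv(path)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    ts = df["timestamp"].to_numpy()
    hz = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    return SensorStream(
        subject_id=subject_id,
        location_id=location_id,
        sampling_hz=hz,
        samples=df[ch_cols].to_numpy(dtype=float),
        labels=[str(v) for v in df["label"]],
    )


def write_feature_csv(pool: Dictionary, path: Union[str, Path]) -> None:
    """``f1..fq,label,subject,location`` feature-table dialect."""
    pool.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path: Union[str, Path], role: str = "related_labeled", domain_id: Optional[str] = None) -> Dictionary:
    return Dictionary.from_frame(pd.read_csv(path, keep_default_na=False), role=role, domain_id=domain_id)
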