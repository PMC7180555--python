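"""Raw-stream preprocessing: smoothing, sliding-window segmentation, features.

The pipeline is the standard inertial-sensing one: a moving-average filter
removes high-frequency noise, a sliding window with overlap segments each
stream, and a fixed battery of per-channel statistics turns each window into
a feature vector.  Defaults follow common practice for 50 Hz wearable data:
2 s windows with 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import Dictionary, FeatureInstance, InputError
from .synthgen import SensorStream

__all__ = [
    "SegmentationConfig",
    "Window",
    "moving_average",
    "segment",
    "extract_features",
    "FEATURES_PER_CHANNEL",
    "feature_names",
    "features_from_stream",
]

#: per-channel statistics, concatenated channel-major
FEATURES_PER_CHANNEL = 8
_STAT_NAMES = ("mean", "std", "min", "max", "median", "rms", "iqr", "zcr")


@dataclass(frozen=True)
class SegmentationConfig:
    """Sliding-window segmentation parameters.

    ``window_seconds`` and ``overlap_fraction`` define window length
    W = round(window_seconds * hz) and stride S = round(W * (1 - overlap)).
    ``smoothing_width`` is the moving-average filter width in samples (odd).
    """

    window_seconds: float = 2.0
    overlap_fraction: float = 0.5
    smoothing_width: int = 5

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ValueError("smoothing_width must be a positive odd integer")


@dataclass
class Window:
    data: np.ndarray  # (W, channels)
    label: Optional[str]
    start: int
    index: int


def moving_average(signal: np.ndarray, width: int) -> np.ndarray:
    """Centered per-channel moving mean; edge windows truncate to the
    available samples, so the output has the input's shape."""
    signal = np.asarray(signal, dtype=float)
    squeeze = signal.ndim == 1
    if squeeze:
        signal = signal[:, None]
    if width < 1 or width % 2 == 0:
        raise InputError("width must be a positive odd integer")
    if width > signal.shape[0]:
        raise InputError("width exceeds signal length")
    out = (
        pd.DataFrame(signal)
        .rolling(window=width, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return out[:, 0] if squeeze else out


def segment(stream: SensorStream, cfg: SegmentationConfig) -> list[Window]:
    """Slice a stream into overlapping windows with majority-vote labels.

    Windows start at 0, S, 2S, …; a trailing partial window is discarded, and
    so is any window whose per-sample labels tie for the majority (those sit
    on activity boundaries and would only inject label noise).
    """
    W = int(round(cfg.window_seconds * stream.sampling_hz))
    S = max(1, int(round(W * (1.0 - cfg.overlap_fraction))))
    n = stream.samples.shape[0]
    if n < W:
        return []
    data = stream.samples
    windows: list[Window] = []
    idx = 0
    for start in range(0, n - W + 1, S):
        chunk_labels = stream.labels[start : start + W]
        counts: dict[str, int] = {}
        for lab in chunk_labels:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        if len(winners) != 1:
            continue  # boundary window: ambiguous label
        windows.append(Window(data=data[start : start + W], label=winners[0], start=start, index=idx))
        idx += 1
    return windows


def extract_features(window: np.ndarray) -> np.ndarray:
    """Fixed 8-statistic battery per channel, channel-major.

    Per channel: mean, standard deviation, min, max, median, RMS,
    interquartile range, and the zero-crossing count of the mean-removed
    channel.  q = 8 × channels.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if window.size == 0:
        raise InputError("window must be non-empty")
    if not np.all(np.isfinite(window)):
        raise InputError("window contains non-finite values")
    feats = []
    for c in range(window.shape[1]):
        x = window[:, c]
        centered = x - x.mean()
        signs = np.sign(centered)
        zc = int(np.sum(signs[:-1] * signs[1:] < 0))
        feats.extend(
            [
                float(x.mean()),
                float(x.std()),
                float(x.min()),
                float(x.max()),
                float(np.median(x)),
                float(np.sqrt(np.mean(x**2))),
                float(np.percentile(x, 75) - np.percentile(x, 25)),
                float(zc),
            ]
        )
    return np.array(feats)


def feature_names(n_channels: int) -> list[str]:
    return [f"ch{c + 1}_{s}" for c in range(n_channels) for s in _STAT_NAMES]


def features_from_stream(
    stream: SensorStream, cfg: SegmentationConfig, role: str = "related_labeled"
) -> Dictionary:
    """Full pipeline: smooth, segment, featurize one stream into a pool."""
    n = stream.samples.shape[0]
    width = min(cfg.smoothing_width, n if n % 2 == 1 else n - 1)
    smoothed = SensorStream(
        subject_id=stream.subject_id,
        location_id=stream.location_id,
        sampling_hz=stream.sampling_hz,
        samples=moving_average(stream.samples, width),
        labels=list(stream.labels),
    )
    insts = []
    for w in segment(smoothed, cfg):
        insts.append(
            FeatureInstance(
                features=extract_features(w.data),
                label=w.label if role != "target_unlabeled" else None,
                subject_id=stream.subject_id,
                location_id=stream.location_id,
                window_index=w.index,
            )
        )
    return Dictionary(insts, role=role, domain_id=f"{stream.subject_id}/{stream.location_id}")
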