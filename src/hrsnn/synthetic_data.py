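"""Labelled spatio-temporal fixtures: class identity lives in motion patterns.

Each clip shows a single bright object (bar or blob) translating across a
small frame with wrap-around; the class determines the motion direction (and
optionally speed), the start position is random per clip, and Gaussian pixel
noise (clipped at zero) is added on top.  Single frames are therefore nearly
uninformative about the class — the label is carried by the temporal
structure, emulating the structure of action-recognition video and
event-camera gesture data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .encoding import FrameSequence
from .engine import SpikeTrainSet
from .exceptions import ConfigurationError, SpecificationError

__all__ = [
    "SyntheticTaskConfig",
    "generate_dataset",
    "generate_event_stream",
    "train_test_split",
]


def _default_directions(n_classes: int) -> List[float]:
    # evenly spaced motion angles, starting rightward
    return [2.0 * math.pi * k / n_classes for k in range(n_classes)]


def _default_speeds(n_classes: int) -> List[float]:
    # classes also differ in speed so event rate is part of the class signature
    return list(np.linspace(0.5, 2.0, n_classes))


@dataclass
class SyntheticTaskConfig:
    """Parameters of the synthetic motion-classification task."""

    n_classes: int = 3
    frames_per_clip: int = 20
    frame_shape: Tuple[int, int] = (16, 16)
    clips_per_class: int = 30
    pixel_noise_sd: float = 0.05
    object_kind: str = "blob"           # {"bar", "blob"}
    directions: Optional[Sequence[float]] = None  # radians, one per class
    speeds: Optional[Sequence[float]] = None      # pixels per frame, one per class
    frame_interval: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise SpecificationError("need at least two classes")
        if self.frames_per_clip < 2:
            raise SpecificationError("need at least two frames per clip")
        if self.pixel_noise_sd < 0:
            raise SpecificationError("pixel_noise_sd must be non-negative")
        if self.object_kind not in ("bar", "blob"):
            raise SpecificationError(f"unknown object kind {self.object_kind!r}")
        if self.directions is None:
            self.directions = _default_directions(self.n_classes)
        if self.speeds is None:
            self.speeds = _default_speeds(self.n_classes)
        if len(self.directions) != self.n_classes or len(self.speeds) != self.n_classes:
            raise SpecificationError("one direction and speed per class required")


def _object_stamp(kind: str) -> np.ndarray:
    if kind == "bar":
        return np.ones((1, 5))
    # 3x3 blob with a soft edge
    stamp = np.array([[0.5, 0.8, 0.5],
                      [0.8, 1.0, 0.8],
                      [0.5, 0.8, 0.5]])
    return stamp


def _render_clip(config: SyntheticTaskConfig, direction: float, speed: float,
                 start: Tuple[float, float], rng: Optional[np.random.Generator]) -> np.ndarray:
    h, w = config.frame_shape
    stamp = _object_stamp(config.object_kind)
    sh, sw = stamp.shape
    if sh > h or sw > w:
        raise ConfigurationError("object larger than the frame")
    dy = speed * math.sin(direction)
    dx = speed * math.cos(direction)
    frames = np.zeros((config.frames_per_clip, h, w))
    r0, c0 = start
    for k in range(config.frames_per_clip):
        r = int(round(r0 + k * dy)) % h
        c = int(round(c0 + k * dx)) % w
        for i in range(sh):
            for j in range(sw):
                frames[k, (r + i) % h, (c + j) % w] += stamp[i, j]
    if rng is not None and config.pixel_noise_sd > 0:
        frames += rng.normal(0.0, config.pixel_noise_sd, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    return frames


def generate_dataset(config: SyntheticTaskConfig) -> List[FrameSequence]:
    """Render all clips: ``clips_per_class`` per class, deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_shape
    clips: List[FrameSequence] = []
    for label in range(config.n_classes):
        for _ in range(config.clips_per_class):
            start = (float(rng.integers(0, h)), float(rng.integers(0, w)))
            frames = _render_clip(config, config.directions[label],
                                  config.speeds[label], start, rng)
            clips.append(FrameSequence(frames, config.frame_interval, label))
    return clips


def generate_event_stream(config: SyntheticTaskConfig) -> List[SpikeTrainSet]:
    """DVS-style event streams: one per clip, events where intensity changes.

    Uses the noiseless rendering of the same clips (same seed and start
    positions), emitting one event per pixel whose intensity changes between
    consecutive frames; the transition index k maps to time
    ``k * frame_interval``.  Matches the encoding module's difference encoder
    at threshold fraction 0 with pool size 1 on the noiseless clip.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_shape
    streams: List[SpikeTrainSet] = []
    duration = (config.frames_per_clip - 1) * config.frame_interval
    for label in range(config.n_classes):
        for _ in range(config.clips_per_class):
            start = (float(rng.integers(0, h)), float(rng.integers(0, w)))
            frames = _render_clip(config, config.directions[label],
                                  config.speeds[label], start, None)
            if config.pixel_noise_sd > 0:
                rng.normal(0.0, config.pixel_noise_sd,
                           size=frames.shape)  # keep the stream aligned with generate_dataset
            diffs = np.abs(np.diff(frames, axis=0))
            steps, rows, cols = np.nonzero(diffs > 0)
            st = SpikeTrainSet(rows * w + cols, steps * config.frame_interval,
                               n_sources=h * w, duration=max(duration, config.frame_interval))
            st.label = label  # type: ignore[attr-defined]
            streams.append(st)
    return streams


def train_test_split(dataset: Sequence, test_fraction: float, seed: int,
                     labels: Optional[Sequence[int]] = None):
    """Stratified split into (train, test): disjoint, exhaustive, deterministic.

    Items must carry a ``label`` attribute unless ``labels`` is given; every
    class needs at least two items so both sides stay non-empty.
    """
    if not (0.0 < test_fraction < 1.0):
        raise SpecificationError("test_fraction must lie in (0, 1)")
    if labels is None:
        labels = [item.label for item in dataset]
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise SpecificationError(
                f"class {cls} has {idx.size} item(s); need >= 2 to stratify")
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    train_idx.sort()
    test_idx.sort()
    return ([dataset[i] for i in train_idx], [dataset[i] for i in test_idx])
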