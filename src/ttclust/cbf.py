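"""Seeded synthetic benchmarks: Cylinder-Bell-Funnel and block fixtures.

The Cylinder-Bell-Funnel (CBF) generator follows the canonical three-class
construction (Saito's benchmark, as distributed through the UCR archive):
each series places a random event of amplitude ``6 + eta`` (eta ~ N(0,1)) at
an integer onset a ~ U[16, 32] lasting d ~ U[32, 96] steps, on top of iid
N(0, noise_sd²) noise, with t indexed 1..n:

    cylinder: (6 + eta) * 1[a, b](t)                 + eps(t)
    bell:     (6 + eta) * 1[a, b](t) * (t - a) / d   + eps(t)
    funnel:   (6 + eta) * 1[a, b](t) * (b - t) / d   + eps(t)

with b = a + d. Same seed, same dataset, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .dataset import TimeSeriesDataset

__all__ = ["CbfConfig", "generate_cbf", "generate_blocks"]

CYLINDER, BELL, FUNNEL = 1, 2, 3


@dataclass(frozen=True)
class CbfConfig:
    """Generation settings for a CBF dataset.

    counts : series per class (cylinder, bell, funnel).
    length : series length n (the benchmark's standard is 128).
    amplitude : base event height (6 in the standard construction).
    noise_sd : standard deviation of the additive Gaussian noise.
    onset_range / duration_range : inclusive integer ranges of the event
        start a and event length d.
    """

    counts: Tuple[int, int, int] = (300, 300, 300)
    length: int = 128
    seed: int = 0
    amplitude: float = 6.0
    amplitude_sd: float = 1.0
    noise_sd: float = 1.0
    onset_range: Tuple[int, int] = (16, 32)
    duration_range: Tuple[int, int] = (32, 96)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("class counts must be >= 0")
        if self.onset_range[0] > self.onset_range[1] or self.duration_range[0] > self.duration_range[1]:
            raise ValueError("ranges must be (low, high) with low <= high")
        if self.onset_range[0] + self.duration_range[0] >= self.length:
            raise ValueError("onset + minimum duration must fall inside the series")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _cbf_shape(kind: int, t: np.ndarray, a: int, b: int, amp: float) -> np.ndarray:
    box = ((t >= a) & (t <= b)).astype(np.float64)
    if kind == CYLINDER:
        return amp * box
    if kind == BELL:
        return amp * box * (t - a) / (b - a)
    return amp * box * (b - t) / (b - a)


def generate_cbf(config: CbfConfig = CbfConfig()) -> TimeSeriesDataset:
    """Generate a labeled CBF dataset (labels 1=cylinder, 2=bell, 3=funnel)."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(1, config.length + 1, dtype=np.float64)
    rows, labels = [], []
    for kind, count in zip((CYLINDER, BELL, FUNNEL), config.counts):
        for _ in range(count):
            eta = rng.standard_normal() * config.amplitude_sd
            eps = rng.standard_normal(config.length) * config.noise_sd
            a = int(rng.integers(config.onset_range[0], config.onset_range[1] + 1))
            d = int(rng.integers(config.duration_range[0], config.duration_range[1] + 1))
            b = min(a + d, config.length)
            rows.append(_cbf_shape(kind, t, a, b, config.amplitude + eta) + eps)
            labels.append(kind)
    return TimeSeriesDataset(np.vstack(rows), labels=np.array(labels, dtype=np.int64))


def generate_blocks(
    k: int,
    size_per_group: int,
    separation: float = 10.0,
    noise_sd: float = 0.0,
    length: int = 16,
    seed: int = 0,
) -> TimeSeriesDataset:
    """Block-structured fixture: ``k`` groups of noisy copies of distinct
    template series; ``separation`` scales the between-template distance
    relative to the within-group noise."""
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    templates = rng.standard_normal((k, length)) * separation
    rows, labels = [], []
    for g in range(k):
        for _ in range(size_per_group):
            rows.append(templates[g] + rng.standard_normal(length) * noise_sd)
            labels.append(g)
    return TimeSeriesDataset(np.vstack(rows), labels=np.array(labels, dtype=np.int64))
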