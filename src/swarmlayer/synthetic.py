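"""Synthetic two-class embedding tables.

Stands in for transfer-learning feature extraction so the rest of the
pipeline is testable without image datasets or pretrained weights.
Class-0 rows are i.i.d. Normal(0, sigma^2) per feature; class-1 rows are
identical except a contiguous leading block of features has its mean
shifted by ``mean_shift * sigma``.  Real CNN embeddings are non-negative
and sparse; the optional ``relu_clip`` maps features through max(0, .) to
mimic that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data import FeatureTable

#: per-class sample totals of the three public histopathology datasets
DATASET_CLASS_COUNTS = {1: (2494, 2698), 2: (89, 439), 3: (201, 495)}

#: embedding dimensions of the backbones used for extraction
BACKBONE_DIMS = {"mobilenetv3": 1280, "efficientnetb3": 1536, "inceptionv2": 1536}

__all__ = [
    "SynthSpec",
    "generate_two_class_features",
    "generate_dataset_fixture",
    "DATASET_CLASS_COUNTS",
    "BACKBONE_DIMS",
]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a two-class Gaussian embedding table.

    ``mean_shift`` is the class-mean gap on the signal-carrying features,
    in units of ``sigma``; ``shifted_fraction`` is the fraction of
    features carrying that signal.
    """

    n_class0: int
    n_class1: int
    dim: int = 1280
    mean_shift: float = 1.0
    sigma: float = 1.0
    shifted_fraction: float = 0.5
    seed: int = 0
    relu_clip: bool = False

    def __post_init__(self) -> None:
        if self.n_class0 < 1 or self.n_class1 < 1:
            raise ValueError("class counts must be positive")
        if self.dim < 5:
            raise ValueError("dim must be at least 5 (swarm transform minimum)")
        if self.mean_shift < 0:
            raise ValueError("mean_shift must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.shifted_fraction <= 1.0:
            raise ValueError("shifted_fraction must lie in (0, 1]")


def generate_two_class_features(spec: SynthSpec) -> FeatureTable:
    """Draw a deterministic two-class table from ``spec``.

    Label 1 is the positive (carcinoma-analog) class throughout.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1, d = spec.n_class0, spec.n_class1, spec.dim
    x0 = rng.normal(0.0, spec.sigma, size=(n0, d))
    x1 = rng.normal(0.0, spec.sigma, size=(n1, d))
    n_shift = math.ceil(spec.shifted_fraction * d)
    x1[:, :n_shift] += spec.mean_shift * spec.sigma
    features = np.vstack([x0, x1])
    if spec.relu_clip:
        features = np.maximum(features, 0.0)
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return FeatureTable(features, labels)


def generate_dataset_fixture(dataset_id: int, dim: int = 1280, **overrides) -> FeatureTable:
    """Table with the exact per-class totals of one of the three public
    datasets (1: 2494/2698, 2: 89/439, 3: 201/495)."""
    if dataset_id not in DATASET_CLASS_COUNTS:
        raise ValueError(f"dataset_id must be one of {sorted(DATASET_CLASS_COUNTS)}")
    n0, n1 = DATASET_CLASS_COUNTS[dataset_id]
    spec = SynthSpec(n_class0=n0, n_class1=n1, dim=dim, seed=dataset_id)
    if overrides:
        spec = replace(spec, **overrides)
    return generate_two_class_features(spec)
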