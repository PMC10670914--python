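"""The intermediate feature-transform layer and its hyperparameter
training.

A fitted layer is a choice of swarm algorithm plus its parameter record;
applying it transforms every row of a feature table independently (one
optimizer run per sample, per-sample seeded).  "Training" the layer is a
two-stage grid search on downstream validation accuracy: first sweep
``max_iter`` with the remaining parameters held at 0.5, then sweep the
algorithm's continuous axes at the chosen ``max_iter``.  The classifier
head is retrained from scratch at every grid point with the same head
seed, so differences in the accuracy surface reflect only the transform.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import FeatureTable
from .head import HeadConfig, predict, train_head
from .rng import sample_stream
from .swarm.driver import ALGORITHMS, AlgoParams, run_swarm_transform
from .swarm.types import EHOParams, MGTOParams, PSOParams

__all__ = [
    "LayerParams",
    "GridSpec",
    "FitResult",
    "transform_table",
    "fit_layer",
    "evaluate_point",
]

#: continuous hyperparameter axes swept in stage 2, per algorithm
_AXES = {
    "gto": ("p", "beta"),
    "mgto": ("p", "beta"),
    "pso": ("w", "c1", "c2"),
    "eho": ("alpha", "beta_e"),
}

_PARAM_TYPES = {"gto": MGTOParams, "mgto": MGTOParams, "pso": PSOParams, "eho": EHOParams}


@dataclass(frozen=True)
class LayerParams:
    """A fully specified transform layer: algorithm, parameters, seed."""

    algorithm: str
    params: AlgoParams
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        expected = _PARAM_TYPES[self.algorithm]
        if not isinstance(self.params, expected):
            raise TypeError(
                f"{self.algorithm} requires {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": asdict(self.params),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerParams":
        ptype = _PARAM_TYPES[d["algorithm"]]
        return cls(d["algorithm"], ptype(**d["params"]), d.get("seed", 0))


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter lattice for layer training.

    ``axes`` maps each continuous parameter name of the algorithm to its
    candidate values; defaults follow a 0.1-step lattice on [0, 1] with
    max_iter in 1..20.
    """

    max_iter_values: Sequence[int] = tuple(range(1, 21))
    axes: Optional[Dict[str, Sequence[float]]] = None

    def __post_init__(self) -> None:
        if not self.max_iter_values:
            raise ValueError("max_iter_values must be non-empty")
        if self.axes is not None and any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("every grid axis must be non-empty")

    def axes_for(self, algorithm: str) -> Dict[str, Sequence[float]]:
        names = _AXES[algorithm]
        if self.axes is None:
            tenths = tuple(round(0.1 * k, 1) for k in range(11))
            return {name: tenths for name in names}
        missing = set(names) - set(self.axes)
        if missing:
            raise ValueError(f"grid is missing axes {sorted(missing)} for {algorithm}")
        return {name: tuple(self.axes[name]) for name in names}


@dataclass
class FitResult:
    """Outcome of layer training: the winning point and the full surface."""

    best_params: LayerParams
    best_validation_accuracy: float
    accuracy_surface: Dict[Tuple[float, ...], float] = field(default_factory=dict)

    def to_json(self) -> str:
        axes = _AXES[self.best_params.algorithm]
        surface = [
            {"max_iter": int(key[0]), **dict(zip(axes, key[1:])), "accuracy": acc}
            for key, acc in sorted(self.accuracy_surface.items())
        ]
        doc = {
            "algorithm": self.best_params.algorithm,
            "params": asdict(self.best_params.params),
            "seed": self.best_params.seed,
            "best_validation_accuracy": self.best_validation_accuracy,
            "accuracy_surface": surface,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        doc = json.loads(text)
        algorithm = doc["algorithm"]
        axes = _AXES[algorithm]
        layer = LayerParams.from_dict(
            {"algorithm": algorithm, "params": doc["params"], "seed": doc["seed"]}
        )
        surface = {
            (point["max_iter"], *(point[a] for a in axes)): point["accuracy"]
            for point in doc["accuracy_surface"]
        }
        return cls(layer, doc["best_validation_accuracy"], surface)


def transform_table(
    table: FeatureTable, layer: LayerParams, sample_indices=None
) -> FeatureTable:
    """Transform every row of ``table`` independently.

    Each row's optimizer stream is seeded by ``(layer.seed, sample_index)``
    so transforming a subset of rows (pass their original indices through
    ``sample_indices``) reproduces the corresponding rows of a full-table
    transform.  Labels and shape are preserved.
    """
    if table.n_features < 5:
        raise ValueError(
            f"swarm transform needs at least 5 feature columns, got {table.n_features}"
        )
    if sample_indices is None:
        sample_indices = range(table.n_samples)
    sample_indices = list(sample_indices)
    if len(sample_indices) != table.n_samples:
        raise ValueError("sample_indices length must match the table's row count")
    out = np.empty_like(table.features)
    for row, idx in enumerate(sample_indices):
        rng = sample_stream(layer.seed, idx)
        out[row] = run_swarm_transform(
            table.features[row], layer.algorithm, layer.params, rng
        )
    return FeatureTable(out, table.labels.copy(), list(table.feature_names))


def _make_params(algorithm: str, max_iter: int, axis_values: Dict[str, float]) -> AlgoParams:
    return _PARAM_TYPES[algorithm](max_iter=int(max_iter), **axis_values)


def evaluate_point(
    train: FeatureTable,
    val: FeatureTable,
    head_config: HeadConfig,
    layer: LayerParams,
) -> float:
    """Validation accuracy of the head trained on the transformed tables."""
    t_train = transform_table(train, layer)
    t_val = transform_table(val, layer)
    head = train_head(t_train, t_val, head_config)
    labels, _ = predict(head, t_val)
    return float((labels == t_val.labels).mean())


def fit_layer(
    train: FeatureTable,
    val: FeatureTable,
    head_config: HeadConfig,
    grid: GridSpec,
    algorithm: str,
    seed: int = 0,
    joint: bool = False,
) -> FitResult:
    """Two-stage grid search for the layer's ideal hyperparameters.

    Stage 1 sweeps ``max_iter`` with every continuous axis at 0.5; stage 2
    sweeps the continuous axes at the stage-1 winner.  With ``joint=True``
    the full cartesian grid is evaluated instead.  The returned best point
    is the argmax over all evaluated points; ties break toward smaller
    ``max_iter`` and then smaller axis values in declaration order.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    if train.n_features != val.n_features:
        raise ValueError("train and val feature dimensionality differ")
    axes = grid.axes_for(algorithm)
    axis_names = list(axes)
    cache: Dict[Tuple[float, ...], float] = {}

    def measure(max_iter: int, values: Dict[str, float]) -> float:
        key = (int(max_iter), *(values[a] for a in axis_names))
        if key not in cache:
            layer = LayerParams(algorithm, _make_params(algorithm, max_iter, values), seed)
            cache[key] = evaluate_point(train, val, head_config, layer)
        return cache[key]

    if joint:
        for m in grid.max_iter_values:
            for combo in itertools.product(*(axes[a] for a in axis_names)):
                measure(m, dict(zip(axis_names, combo)))
    else:
        # stage 1: sweep max_iter with every continuous axis held at 0.5
        midpoint = {a: 0.5 for a in axis_names}
        stage1 = [(measure(m, midpoint), m) for m in grid.max_iter_values]
        best_m = min(stage1, key=lambda t: (-t[0], t[1]))[1]
        # stage 2: sweep the continuous axes at the stage-1 winner
        for combo in itertools.product(*(axes[a] for a in axis_names)):
            measure(best_m, dict(zip(axis_names, combo)))

    # the recorded surface holds grid members only; midpoint probes that are
    # not grid points were scaffolding for stage 1 and stay out, so the best
    # point is always an element of the requested grid
    surface = {
        key: acc
        for key, acc in cache.items()
        if all(key[1 + j] in axes[a] for j, a in enumerate(axis_names))
    }
    best_key = min(surface, key=lambda k: (-surface[k],) + k)
    best_values = dict(zip(axis_names, best_key[1:]))
    best_layer = LayerParams(
        algorithm, _make_params(algorithm, int(best_key[0]), best_values), seed
    )
    return FitResult(best_layer, surface[best_key], surface)
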