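"""End-to-end pipeline: split -> (optional) layer fit -> transform ->
head training -> test-set metrics, with a no-layer baseline run under the
same seeds so the report can state the relative accuracy change."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from .data import FeatureTable, SplitSpec, read_feature_table, stratified_split
from .head import HeadConfig, predict, train_head
from .metrics import confusion_and_metrics, pct_accuracy_increase
from .synthetic import SynthSpec, generate_two_class_features
from .transform import FitResult, GridSpec, LayerParams, fit_layer, transform_table

logger = logging.getLogger("swarmlayer")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``table``, ``table_path`` or ``synth`` supplies the
    input features.  ``algorithm`` is one of gto/mgto/pso/eho or "none"
    for a baseline-only run.  If ``layer_params`` is given the grid
    search is skipped and those parameters are used directly.
    """

    algorithm: str = "none"
    table: Optional[FeatureTable] = None
    table_path: Optional[str] = None
    synth: Optional[SynthSpec] = None
    split: SplitSpec = field(default_factory=SplitSpec)
    head: HeadConfig = field(default_factory=HeadConfig)
    grid: Optional[GridSpec] = None
    layer_params: Optional[LayerParams] = None
    seed: int = 0


class PipelineError(RuntimeError):
    """Error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise PipelineError(name, exc) from exc

    return wrap


def _load(config: PipelineConfig) -> FeatureTable:
    sources = [s for s in (config.table, config.table_path, config.synth) if s is not None]
    if len(sources) != 1:
        raise ValueError("exactly one of table, table_path or synth must be set")
    if config.table is not None:
        return config.table
    if config.table_path is not None:
        return read_feature_table(config.table_path)
    return generate_two_class_features(config.synth)


def _evaluate(train, val, test, head_cfg):
    head = train_head(train, val, head_cfg)
    labels, _ = predict(head, test)
    return confusion_and_metrics(test.labels, labels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and return a JSON-serializable report.

    The report carries the baseline (no-layer) test metrics, and — when an
    algorithm is chosen — the fitted layer parameters, the with-layer test
    metrics and the percent accuracy increase over the baseline.
    """
    table = _stage("load")(_load, config)
    splits = _stage("split")(stratified_split, table, config.split)
    logger.info(
        "split sizes: train=%d val=%d test=%d (seed=%d)",
        splits.train.n_samples, splits.val.n_samples, splits.test.n_samples,
        config.split.seed,
    )

    baseline = _stage("baseline-head")(
        _evaluate, splits.train, splits.val, splits.test, config.head
    )
    report = {
        "seed": config.seed,
        "split": {
            "train": splits.train.n_samples,
            "val": splits.val.n_samples,
            "test": splits.test.n_samples,
            "seed": config.split.seed,
        },
        "baseline_metrics": baseline.to_dict(),
        "algorithm": config.algorithm,
    }

    if config.algorithm == "none":
        report["pct_accuracy_increase"] = 0.0
        return json.loads(json.dumps(report, sort_keys=True))

    if config.layer_params is not None:
        layer = config.layer_params
        report["layer"] = layer.to_dict()
    else:
        grid = config.grid if config.grid is not None else GridSpec()
        fit: FitResult = _stage("fit-layer")(
            fit_layer, splits.train, splits.val, config.head, grid,
            config.algorithm, config.seed,
        )
        layer = fit.best_params
        report["layer"] = layer.to_dict()
        report["layer_fit"] = {
            "best_validation_accuracy": fit.best_validation_accuracy,
            "n_grid_points": len(fit.accuracy_surface),
        }

    t_train = _stage("transform")(transform_table, splits.train, layer)
    t_val = _stage("transform")(transform_table, splits.val, layer)
    t_test = _stage("transform")(transform_table, splits.test, layer)
    with_layer = _stage("head")(_evaluate, t_train, t_val, t_test, config.head)
    report["metrics"] = with_layer.to_dict()
    report["pct_accuracy_increase"] = pct_accuracy_increase(
        baseline.accuracy, with_layer.accuracy
    )
    return json.loads(json.dumps(report, sort_keys=True))
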