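"""End-to-end driver: window -> features -> nested CV -> report."""

from __future__ import annotations

from typing import Sequence

from .evaluation import EvaluationReport, aggregate_report
from .features import FeatureConfig
from .model import CVConfig, HyperParams, nested_cv
from .windowing import EarlyWindowDataset, WindowSpec, subset_and_trim

__all__ = ["evaluate_window", "evaluate_grid"]


def evaluate_window(
    dataset: EarlyWindowDataset,
    grid: Sequence[HyperParams] | None = None,
    cv: CVConfig | None = None,
    feature_config: FeatureConfig | None = None,
    threshold: float = 0.50,
) -> EvaluationReport:
    """Nested-CV evaluation of one early-window dataset."""
    folds = nested_cv(dataset, grid, cv, feature_config)
    return aggregate_report(folds, descriptives=dataset.descriptives(), threshold=threshold)


def evaluate_grid(
    streams,
    specs: Sequence[WindowSpec],
    grid: Sequence[HyperParams] | None = None,
    cv: CVConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> dict[str, EvaluationReport]:
    """Evaluate every window in a grid; keys are window spec strings."""
    reports = {}
    for spec in specs:
        dataset = subset_and_trim(streams, spec)
        reports[str(spec)] = evaluate_window(dataset, grid, cv, feature_config)
    return reports
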