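"""High-level analysis drivers tying the modules together."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureSeries, WindowConfig, pool_features, sliding_features
from .segmentation import (
    LabelSeries,
    StateModel,
    classify_windows,
    fit_state_model,
    state_fractions,
    windows_to_timepoints,
)
from .substates import AlphaMixtureFit, fit_alpha_mixture, split_slow_fast
from .trajio import Trajectory, filter_by_duration


@dataclass
class SegmentationResult:
    model: StateModel
    series: list[FeatureSeries]
    labels: list[LabelSeries]
    fractions_windows: dict[str, float]
    fractions_trajectories: dict[str, float]


def segment_dataset(
    trajs: list[Trajectory],
    config: WindowConfig | None = None,
    seed: int = 0,
) -> SegmentationResult:
    """Stage-1 analysis: features, mixture fit, per-frame labels, fractions."""
    cfg = config or WindowConfig()
    series = [sliding_features(t, cfg) for t in trajs]
    model = fit_state_model(pool_features(series), seed=seed)
    labels = [
        windows_to_timepoints(classify_windows(model, s), s) for s in series if len(s)
    ]
    return SegmentationResult(
        model=model,
        series=series,
        labels=labels,
        fractions_windows=state_fractions(labels, by="windows"),
        fractions_trajectories=state_fractions(labels, by="trajectories"),
    )


@dataclass
class TwoStageResult:
    model: StateModel
    alpha_fit: AlphaMixtureFit
    series: list[FeatureSeries]
    n_slow: int
    n_fast: int

    @property
    def proportions(self) -> dict[str, float]:
        return self.alpha_fit.proportions


def two_stage_analysis(
    trajs: list[Trajectory],
    config: WindowConfig | None = None,
    seed: int = 0,
    min_duration: float = 5.0,
    n_boot: int = 1000,
) -> TwoStageResult:
    """Stage 1 + Stage 2 on chromatin-bound (500 ms) data.

    Trajectories lasting no more than ``min_duration`` seconds are dropped;
    the Stage-1 mixture splits windows slow/fast and the Stage-2 alpha
    mixture resolves F1/F2 within the fast class.
    """
    cfg = config or WindowConfig()
    kept = filter_by_duration(trajs, min_duration)
    series = [sliding_features(t, cfg) for t in kept]
    model = fit_state_model(pool_features(series), seed=seed)
    slow, fast = split_slow_fast(model, series)
    fit = fit_alpha_mixture(
        fast["alpha"].to_numpy(), len(slow), seed=seed, n_boot=n_boot
    )
    return TwoStageResult(
        model=model, alpha_fit=fit, series=series, n_slow=len(slow), n_fast=len(fast)
    )


def segmentation_accuracy(
    result: SegmentationResult, truth: dict[str, np.ndarray]
) -> float:
    """Per-frame accuracy of assigned labels against ground-truth labels."""
    n_ok = n_tot = 0
    for ls in result.labels:
        t = truth.get(ls.traj_id)
        if t is None:
            continue
        mask = ls.labels != "unassigned"
        n_ok += int(np.sum(ls.labels[mask] == np.asarray(t, dtype=object)[mask]))
        n_tot += int(mask.sum())
    if n_tot == 0:
        raise ValueError("no assigned frames overlap the truth labels")
    return n_ok / n_tot
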