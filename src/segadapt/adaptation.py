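"""Feedback parameter adaptation: exhaustive grid search of the pipeline
parameters against a quality criterion.

Modes: per-image adaptation (maximize ``Q`` or ``Q_feat`` for one image),
robust adaptation (maximize the series-mean ``R`` with one fixed parameter
set), best-of selection between a feedforward baseline and the adapted
result, a step-size sensitivity sweep, and the bundled two-method
benchmark experiment.

The optimizer is a deliberate exhaustive grid search; the ``criterion``
argument is a pluggable scoring object so other optimizers can reuse the
same surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .benchmark import BenchmarkSeries
from .evaluation import FuzzySpec, quality_Q, quality_feat, robustness_R
from .features import (
    FEATURE_NAMES,
    Prototypes,
    build_prototypes,
    classify_objects,
    extract_features,
)
from .pipeline import (
    METHODS,
    ParameterError,
    ParameterVector,
    auto_edge_threshold,
    label_mask,
    mask_from_magnitude,
    mean_filter,
    opening,
    run_pipeline,
    sobel_magnitude,
    threshold_segment,
)

__all__ = [
    "GridError",
    "ParameterGrid",
    "AdaptationResult",
    "ExplicitQuality",
    "FeatureQuality",
    "adapt_per_image",
    "adapt_robust",
    "evaluate_fixed",
    "best_of",
    "delta_sweep",
    "case1_experiment",
    "OTSU_T_BOUNDS",
    "EDGE_T_BOUNDS",
    "EDGE_T_BOUNDS_WIDE",
    "MULTI_GRID_DEFAULTS",
]

# default search ranges for the bundled experiment
OTSU_T_BOUNDS = (0.1, 0.78, 0.02)  # (t_low, t_high, delta)
EDGE_T_BOUNDS = (0.01, 0.21, 0.01)
# the useful edge-threshold band depends on scene contrast; the synthetic
# scenes have sharper steps than low-contrast photographs, so their band
# extends higher
EDGE_T_BOUNDS_WIDE = (0.01, 0.45, 0.01)
MULTI_GRID_DEFAULTS = {
    "w_values": (3, 5),  # window sizes must be odd; even values are invalid
    "s_values": (3, 5, 7, 9, 11),
    "t_bounds": (0.01, 0.99, 0.04),
}


class GridError(ValueError):
    """Invalid parameter grid."""


def _t_values(t_low: float, t_high: float, delta: float) -> Tuple[float, ...]:
    if not t_low < t_high:
        raise GridError(f"need t_low < t_high, got [{t_low}, {t_high}]")
    if not 0.0 < delta < t_high - t_low:
        raise GridError(f"delta {delta} outside (0, {t_high - t_low})")
    values = []
    k = 0
    while True:
        # decimal rounding keeps nested grids (delta vs 2*delta) bit-identical
        t = round(t_low + k * delta, 12)
        if t > t_high + 1e-12:
            break
        values.append(min(t, t_high))
        k += 1
    return tuple(values)


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian grid over (w, t, s); iterated row-major (w, t, s)."""

    w_values: Tuple[int, ...] = (1,)
    t_values: Tuple[float, ...] = (0.5,)
    s_values: Tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "w_values", tuple(self.w_values))
        object.__setattr__(self, "t_values", tuple(self.t_values))
        object.__setattr__(self, "s_values", tuple(self.s_values))
        if not (self.w_values and self.t_values and self.s_values):
            raise GridError("grid must be nonempty in every dimension")

    @classmethod
    def from_bounds(
        cls,
        t_low: float,
        t_high: float,
        delta: float,
        w_values: Sequence[int] = (1,),
        s_values: Sequence[int] = (1,),
    ) -> "ParameterGrid":
        return cls(tuple(w_values), _t_values(t_low, t_high, delta), tuple(s_values))

    def points(self) -> List[ParameterVector]:
        return [
            ParameterVector(w=w, t=t, s=s)
            for w in self.w_values
            for t in self.t_values
            for s in self.s_values
        ]

    def __len__(self) -> int:
        return len(self.w_values) * len(self.t_values) * len(self.s_values)


@dataclass(frozen=True)
class AdaptationResult:
    """Outcome of a search (or of a single fixed evaluation).

    ``trace`` holds every evaluated point with its criterion value so the
    search is auditable; ``score`` always equals ``max`` over the trace.
    """

    params: ParameterVector
    score: float
    trace: Tuple[Tuple[ParameterVector, float], ...]
    method: str
    criterion: str
    label: str = "auto"


class ExplicitQuality:
    """Criterion ``Q`` against explicit pixel ground truth.

    When ``prototypes`` are supplied, segmented objects are classified by
    nearest prototype and the misclassification term enters the score.
    """

    name = "Q"

    def __init__(
        self,
        gt_labels: np.ndarray,
        gt_class_map: Optional[Dict[int, int]] = None,
        prototypes: Optional[Prototypes] = None,
    ):
        self.gt_labels = np.asarray(gt_labels)
        self.gt_class_map = dict(gt_class_map) if gt_class_map else None
        self.prototypes = prototypes
        if prototypes is not None and gt_class_map is None:
            raise ValueError("prototypes require a ground-truth class map")
        self._n_gt = len(np.unique(self.gt_labels[self.gt_labels > 0]))

    def score(self, labels: np.ndarray) -> float:
        # fast path: if the count penalty alone saturates (mu1 = 0), Q is 0
        # regardless of the remaining terms -- skip the expensive features
        n_pred = int(labels.max())
        n_gt = self._n_gt
        if n_gt > 0 and abs(n_pred - n_gt) >= max(n_gt, 1):
            return 0.0
        pred_classes = None
        if self.prototypes is not None:
            pred_classes = classify_objects(extract_features(labels), self.prototypes)
        return quality_Q(
            labels, self.gt_labels, self.gt_class_map, pred_classes
        ).Q


class FeatureQuality:
    """Criterion ``Q_feat`` against an abstract (fuzzy) ground truth."""

    name = "Q_feat"

    def __init__(self, spec: FuzzySpec):
        self.spec = spec

    def score(self, labels: np.ndarray) -> float:
        return quality_feat(extract_features(labels), self.spec)


# in feedback mode the t-grid overrides the data-driven Otsu threshold, so
# the searched stage is plain intensity thresholding
_FEEDBACK_STAGE = {
    "manual_threshold": "manual_threshold",
    "otsu": "manual_threshold",
    "sobel_edge": "sobel_edge",
}

class _StageCache:
    """Per-image cache of the w-dependent pipeline stages.

    Produces results bit-identical to :func:`segadapt.pipeline.run_pipeline`
    while avoiding repeated convolutions across grid points.
    """

    def __init__(self, image: np.ndarray, stage: str):
        self.image = image
        self.stage = stage
        self._smoothed: Dict[int, np.ndarray] = {}
        self._magnitude: Dict[int, np.ndarray] = {}

    def labels(self, p: ParameterVector) -> np.ndarray:
        if p.w not in self._smoothed:
            self._smoothed[p.w] = mean_filter(self.image, p.w)
        smoothed = self._smoothed[p.w]
        if self.stage == "manual_threshold":
            mask = threshold_segment(smoothed, p.t)
        else:
            if p.w not in self._magnitude:
                self._magnitude[p.w] = sobel_magnitude(smoothed)
            mask = mask_from_magnitude(self._magnitude[p.w], p.t)
        return label_mask(opening(mask, p.s))


def _better(score: float, p: ParameterVector, best: Tuple[float, ParameterVector]) -> bool:
    # ties broken by smallest t, then smallest w, then smallest s
    if score != best[0]:
        return score > best[0]
    return (p.t, p.w, p.s) < (best[1].t, best[1].w, best[1].s)


def adapt_per_image(
    image: np.ndarray, method: str, grid: ParameterGrid, criterion
) -> AdaptationResult:
    """Exhaustively score the pipeline at every grid point on one image and
    return the criterion maximizer."""
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}")
    cache = _StageCache(image, _FEEDBACK_STAGE[method])
    trace: List[Tuple[ParameterVector, float]] = []
    best: Optional[Tuple[float, ParameterVector]] = None
    for p in grid.points():
        value = float(criterion.score(cache.labels(p)))
        trace.append((p, value))
        if best is None or _better(value, p, best):
            best = (value, p)
    assert best is not None
    return AdaptationResult(
        params=best[1],
        score=best[0],
        trace=tuple(trace),
        method=method,
        criterion=criterion.name,
    )


def _series_images(series: Union[BenchmarkSeries, Sequence[np.ndarray]]):
    if isinstance(series, BenchmarkSeries):
        return list(series.images)
    return list(series)


def adapt_robust(
    series: Union[BenchmarkSeries, Sequence[np.ndarray]],
    method: str,
    grid: ParameterGrid,
    criterion,
) -> AdaptationResult:
    """Find the single parameter set maximizing the mean quality ``R`` over
    a whole artifact series."""
    images = _series_images(series)
    if not images:
        raise ValueError("empty series")
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}")
    caches = [_StageCache(img, _FEEDBACK_STAGE[method]) for img in images]
    trace: List[Tuple[ParameterVector, float]] = []
    best: Optional[Tuple[float, ParameterVector]] = None
    for p in grid.points():
        r = robustness_R([float(criterion.score(c.labels(p))) for c in caches])
        trace.append((p, r))
        if best is None or _better(r, p, best):
            best = (r, p)
    assert best is not None
    return AdaptationResult(
        params=best[1],
        score=best[0],
        trace=tuple(trace),
        method=method,
        criterion=criterion.name,
        label="rob",
    )


def evaluate_fixed(
    image: np.ndarray,
    p: ParameterVector,
    method: str,
    criterion,
    label: str = "std",
) -> AdaptationResult:
    """Score a single fixed parameter set (feedforward baseline)."""
    value = float(criterion.score(run_pipeline(image, p, method)))
    return AdaptationResult(
        params=p,
        score=value,
        trace=((p, value),),
        method=method,
        criterion=criterion.name,
        label=label,
    )


def best_of(feedforward: AdaptationResult, feedback: AdaptationResult) -> AdaptationResult:
    """The better-scoring of a feedforward and a feedback result; ties go to
    the feedback result, so the choice never scores below the baseline."""
    if feedforward.criterion != feedback.criterion:
        raise ValueError(
            f"criterion mismatch: {feedforward.criterion!r} vs {feedback.criterion!r}"
        )
    return feedback if feedback.score >= feedforward.score else feedforward


def delta_sweep(
    series: Union[BenchmarkSeries, Sequence[np.ndarray]],
    method: str,
    deltas: Sequence[float],
    t_low: float,
    t_high: float,
    criterion,
    w_values: Sequence[int] = (1,),
    s_values: Sequence[int] = (1,),
) -> pd.DataFrame:
    """Step-size sensitivity: per-image adaptation at each grid step size,
    reporting the mean achieved quality ``R``.

    With aligned bounds coarser grids are subsets of finer ones, so ``R`` is
    non-increasing along a nested delta sequence.
    """
    images = _series_images(series)
    rows = []
    for delta in deltas:
        grid = ParameterGrid.from_bounds(t_low, t_high, delta, w_values, s_values)
        qs = [adapt_per_image(img, method, grid, criterion).score for img in images]
        rows.append({"delta": float(delta), "R": robustness_R(qs), "n_grid": len(grid)})
    return pd.DataFrame(rows)


def _std_result(
    image: np.ndarray, method: str, criterion, s: int = 1
) -> AdaptationResult:
    """Feedforward baseline: the method's own data-driven threshold, w=1 and
    a fixed opening size shared with the feedback variant."""
    if method == "otsu":
        return evaluate_fixed(image, ParameterVector(1, 0.5, s), "otsu", criterion)
    t_std = auto_edge_threshold(mean_filter(image, 1))
    return evaluate_fixed(image, ParameterVector(1, t_std, s), "sobel_edge", criterion)


def case1_experiment(
    series: BenchmarkSeries,
    methods: Sequence[str] = ("otsu", "sobel_edge"),
    include_multi: bool = True,
    use_best_of: bool = True,
    class_features: Sequence[str] = FEATURE_NAMES,
    multi_class_features: Sequence[str] = ("area", "eccentricity", "solidity"),
    post_s: int = 3,
    otsu_t_bounds: Tuple[float, float, float] = OTSU_T_BOUNDS,
    edge_t_bounds: Tuple[float, float, float] = EDGE_T_BOUNDS_WIDE,
) -> Dict[str, object]:
    """Feedforward vs feedback comparison over a graded artifact series.

    Emits per-level quality for the standard, per-image adapted and robust
    variants of each method, plus (optionally) simultaneous (w, t, s)
    adaptation, and the per-method robustness means.  ``post_s`` is the
    fixed opening size shared by the feedforward baselines and the
    single-parameter feedback variants (the post-processing structure is
    identical with and without feedback).
    """
    gt = series.ground_truth
    protos = build_prototypes(gt.labels, gt.class_map, class_features)
    criterion = ExplicitQuality(gt.labels, gt.class_map, protos)
    multi_protos = build_prototypes(gt.labels, gt.class_map, multi_class_features)
    multi_criterion = ExplicitQuality(gt.labels, gt.class_map, multi_protos)

    grids = {
        "otsu": ParameterGrid.from_bounds(*otsu_t_bounds, s_values=(post_s,)),
        "sobel_edge": ParameterGrid.from_bounds(*edge_t_bounds, s_values=(post_s,)),
    }
    short = {"otsu": "otsu", "sobel_edge": "edge"}

    columns: Dict[str, List[float]] = {}
    robust_params: Dict[str, ParameterVector] = {}

    for method in methods:
        tag = short[method]
        rob = adapt_robust(series, method, grids[method], criterion)
        robust_params[tag] = rob.params
        q_std, q_auto, q_auto_raw, q_rob = [], [], [], []
        for img in series.images:
            std = _std_result(img, method, criterion, s=post_s)
            auto = adapt_per_image(img, method, grids[method], criterion)
            chosen = best_of(std, auto) if use_best_of else auto
            q_std.append(std.score)
            q_auto.append(chosen.score)
            q_auto_raw.append(auto.score)
            q_rob.append(
                evaluate_fixed(img, rob.params, method, criterion, "rob").score
            )
        columns[f"Q_std_{tag}"] = q_std
        columns[f"Q_auto_{tag}"] = q_auto
        columns[f"Q_auto_raw_{tag}"] = q_auto_raw
        columns[f"Q_rob_{tag}"] = q_rob

    if include_multi:
        multi_grid = ParameterGrid.from_bounds(
            *MULTI_GRID_DEFAULTS["t_bounds"],
            w_values=MULTI_GRID_DEFAULTS["w_values"],
            s_values=MULTI_GRID_DEFAULTS["s_values"],
        )
        q_multi = []
        for img in series.images:
            auto = adapt_per_image(img, "manual_threshold", multi_grid, multi_criterion)
            if use_best_of:
                std = _std_result(img, "otsu", multi_criterion, s=post_s)
                auto = best_of(std, auto)
            q_multi.append(auto.score)
        columns["Q_multi_auto"] = q_multi

    table = pd.DataFrame(
        {
            "scene": series.spec.scene_id,
            "b": series.b_levels,
            "n": series.n_levels,
            "A": series.artifact_levels,
            **columns,
        }
    )
    robustness = {
        name.replace("Q_", "R_"): robustness_R(vals) for name, vals in columns.items()
    }
    return {"table": table, "robustness": robustness, "robust_params": robust_params}
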