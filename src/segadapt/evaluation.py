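"""Quality criteria for segmentation results.

Two families are provided:

* explicit ground truth: raw measures ``q1`` (object-count deviation),
  ``q2`` (non-overlapping pixels) and ``q3`` (misclassified pixels) are
  fuzzified to ``mu_i = max(0, 1 - q_i)`` and aggregated to
  ``Q = mu1 * mu2 * mu3``; robustness ``R`` is the arithmetic mean of ``Q``
  over an artifact series;
* abstract ground truth: per-feature trapezoidal memberships ``theta`` and
  an object-count term ``theta_c`` aggregated to ``Q_feat``.

The exact raw-measure forms are documented stand-ins; they preserve the
semantics (count penalty, overlap penalty, classification penalty, each
mapped to [0, 1]) and only their orderings are relied upon downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FuzzySpecError",
    "FuzzySpec",
    "QualityReport",
    "trapezoid_membership",
    "match_objects",
    "quality_Q",
    "robustness_R",
    "quality_feat",
    "fuzzy_products",
    "rank_by_product",
]


class FuzzySpecError(ValueError):
    """Invalid trapezoid edges or fuzzy specification."""


def trapezoid_membership(f: float, a: float, b: float, c: float, d: float) -> float:
    """Trapezoidal fuzzy membership with edges ``a <= b <= c <= d``.

    Zero below ``a`` and above ``d``, linear ramps on ``(a, b]`` and
    ``[c, d)``, one on the plateau ``[b, c]``.  Coincident edges give step
    sides; on a degenerate edge the plateau value wins.
    """
    if not a <= b <= c <= d:
        raise FuzzySpecError(f"trapezoid edges must be ordered, got {(a, b, c, d)}")
    if f < a or f > d:
        return 0.0
    if b <= f <= c:
        return 1.0
    if f < b:
        return (f - a) / (b - a)
    return (d - f) / (d - c)


@dataclass(frozen=True)
class FuzzySpec:
    """Abstract ground truth: per-feature trapezoid edges, an optional
    object-count trapezoid and an optional known target count ``n_c``.

    ``feature_edges`` maps a feature name (attribute of a feature record,
    e.g. ``"area"``) to its ``(a, b, c, d)`` edges.  When ``n_c`` is known
    the count term is identically 1 and only the top-``n_c`` objects enter
    the score.
    """

    feature_edges: Mapping[str, Tuple[float, float, float, float]]
    count_edges: Optional[Tuple[float, float, float, float]] = None
    n_c: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_edges", dict(self.feature_edges))
        if not self.feature_edges:
            raise FuzzySpecError("at least one feature trapezoid is required")
        for name, edges in self.feature_edges.items():
            a, b, c, d = edges
            if not a <= b <= c <= d:
                raise FuzzySpecError(f"unordered edges for {name!r}: {edges}")
        if self.count_edges is not None:
            a, b, c, d = self.count_edges
            if not a <= b <= c <= d:
                raise FuzzySpecError(f"unordered count edges: {self.count_edges}")
        if self.n_c is not None and self.n_c < 1:
            raise FuzzySpecError("n_c must be >= 1 when given")

    def product(self, record) -> float:
        """Product of per-feature memberships for one feature record."""
        out = 1.0
        for name, (a, b, c, d) in self.feature_edges.items():
            out *= trapezoid_membership(float(getattr(record, name)), a, b, c, d)
        return out

    def count_term(self, n_t: int) -> float:
        if self.n_c is not None or self.count_edges is None:
            return 1.0
        return trapezoid_membership(float(n_t), *self.count_edges)


@dataclass(frozen=True)
class QualityReport:
    """Raw measures, their fuzzified values and the aggregate ``Q``."""

    q1: float
    q2: float
    q3: float
    mu1: float
    mu2: float
    mu3: float
    Q: float
    n_pred: int
    n_gt: int
    n_matched: int
    jaccard: float  # global foreground Jaccard index, diagnostic only


def match_objects(
    pred: np.ndarray, gt: np.ndarray
) -> List[Tuple[int, int, int]]:
    """Greedy one-to-one matching of predicted to ground-truth objects by
    descending pixel overlap.

    Returns ``(pred_id, gt_id, overlap)`` triples; zero-overlap pairs are
    never matched.  Ties are broken by lower predicted id, then lower
    ground-truth id, making the result deterministic.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    both = (pred > 0) & (gt > 0)
    if not both.any():
        return []
    pairs, counts = np.unique(
        np.stack([pred[both], gt[both]]), axis=1, return_counts=True
    )
    order = np.lexsort((pairs[1], pairs[0], -counts))
    matches: List[Tuple[int, int, int]] = []
    used_pred: set = set()
    used_gt: set = set()
    for idx in order:
        pid, gid = int(pairs[0, idx]), int(pairs[1, idx])
        if pid in used_pred or gid in used_gt:
            continue
        used_pred.add(pid)
        used_gt.add(gid)
        matches.append((pid, gid, int(counts[idx])))
    return matches


def _sizes(labels: np.ndarray) -> Dict[int, int]:
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def quality_Q(
    pred: np.ndarray,
    gt_labels: np.ndarray,
    gt_classes: Optional[Mapping[int, int]] = None,
    pred_classes: Optional[Mapping[int, int]] = None,
) -> QualityReport:
    """Score a labeled prediction against explicit pixel ground truth.

    Raw measures:

    * ``q1 = |n_pred - n_gt| / max(n_gt, 1)``
    * ``q2`` = (pixels of unmatched ground-truth objects + pixels of
      unmatched predicted objects + symmetric difference over matched
      pairs) / total ground-truth object pixels
    * ``q3`` = misclassified pixels among matched predicted objects / total
      matched predicted pixels (1 if nothing matched); computed only when
      class maps are supplied, otherwise neutral (0).

    ``mu_i = max(0, 1 - q_i)`` and ``Q = mu1 * mu2 * mu3``.  An empty
    ground truth scores 1 against an empty prediction and 0 otherwise.
    """
    pred = np.asarray(pred)
    gt_labels = np.asarray(gt_labels)
    if pred.shape != gt_labels.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt_labels.shape}")
    pred_sizes = _sizes(pred)
    gt_sizes = _sizes(gt_labels)
    n_pred, n_gt = len(pred_sizes), len(gt_sizes)

    pred_fg = pred > 0
    gt_fg = gt_labels > 0
    union = int((pred_fg | gt_fg).sum())
    jaccard = float((pred_fg & gt_fg).sum() / union) if union else 1.0

    if n_gt == 0 and n_pred == 0:
        return QualityReport(0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0, 0, 0, jaccard)

    matches = match_objects(pred, gt_labels)
    matched_pred = {pid for pid, _, _ in matches}
    matched_gt = {gid for _, gid, _ in matches}

    q1 = abs(n_pred - n_gt) / max(n_gt, 1)

    gt_total = sum(gt_sizes.values())
    mismatch = sum(c for i, c in gt_sizes.items() if i not in matched_gt)
    mismatch += sum(c for i, c in pred_sizes.items() if i not in matched_pred)
    for pid, gid, ov in matches:
        mismatch += pred_sizes[pid] + gt_sizes[gid] - 2 * ov
    q2 = mismatch / gt_total if gt_total else (1.0 if pred_sizes else 0.0)

    if gt_classes is None or pred_classes is None:
        q3 = 0.0
    elif not matches:
        q3 = 1.0
    else:
        matched_pixels = sum(pred_sizes[pid] for pid, _, _ in matches)
        wrong = sum(
            pred_sizes[pid]
            for pid, gid, _ in matches
            if pred_classes.get(pid) != gt_classes.get(gid)
        )
        q3 = wrong / matched_pixels

    mu1 = max(0.0, 1.0 - q1)
    mu2 = max(0.0, 1.0 - q2)
    mu3 = max(0.0, 1.0 - q3)
    return QualityReport(
        q1=q1,
        q2=q2,
        q3=q3,
        mu1=mu1,
        mu2=mu2,
        mu3=mu3,
        Q=mu1 * mu2 * mu3,
        n_pred=n_pred,
        n_gt=n_gt,
        n_matched=len(matches),
        jaccard=jaccard,
    )


def robustness_R(q_series: Sequence[float]) -> float:
    """Arithmetic mean of a quality series over all artifact levels.

    Uses an exactly-rounded sum so the result is bit-identical under any
    permutation of the series.
    """
    if len(q_series) == 0:
        raise ValueError("empty quality series")
    return math.fsum(float(q) for q in q_series) / len(q_series)


def fuzzy_products(records: Sequence, spec: FuzzySpec) -> List[float]:
    """Per-object product of feature memberships, in record order."""
    return [spec.product(rec) for rec in records]


def rank_by_product(records: Sequence, spec: FuzzySpec) -> List[Tuple[float, int]]:
    """Indices of ``records`` sorted by descending membership product, ties
    broken by larger area then lower object id; returns (product, index)."""
    products = fuzzy_products(records, spec)
    order = sorted(
        range(len(records)),
        key=lambda i: (
            -products[i],
            -float(getattr(records[i], "area", 0.0)),
            getattr(records[i], "object_id", i),
        ),
    )
    return [(products[i], i) for i in order]


def quality_feat(records: Sequence, spec: FuzzySpec) -> float:
    """Abstract-ground-truth quality of a set of feature records.

    ``Q_feat = theta_c(n_t) / n_t * sum_i prod_j theta(f_ij)``.  When
    ``spec.n_c`` is known the count term is 1 and the sum runs over the
    top-``n_c`` objects only.  ``n_t == 0`` scores 0 by convention.
    """
    n_t = len(records)
    if n_t == 0:
        return 0.0
    ranked = rank_by_product(records, spec)
    if spec.n_c is not None:
        total = sum(prod for prod, _ in ranked[: spec.n_c])
        theta_c = 1.0
    else:
        total = sum(prod for prod, _ in ranked)
        theta_c = spec.count_term(n_t)
    return theta_c * total / n_t
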