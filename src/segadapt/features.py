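"""Per-object feature extraction and classification against references."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .evaluation import FuzzySpec, rank_by_product

__all__ = [
    "FEATURE_NAMES",
    "FeatureRecord",
    "Prototypes",
    "extract_features",
    "build_prototypes",
    "classify_objects",
    "select_target_objects",
]

#: canonical feature order used throughout the package
FEATURE_NAMES = ("area", "eccentricity", "solidity", "extent", "minor_axis_length")


@dataclass(frozen=True)
class FeatureRecord:
    """Shape features of one segmented object.

    Eccentricity, solidity and extent come from the standard
    normalized-second-central-moment ellipse / convex hull / bounding box
    definitions.
    """

    object_id: int
    area: float
    eccentricity: float
    solidity: float
    extent: float
    minor_axis_length: float

    def vector(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([float(getattr(self, n)) for n in names], dtype=float)


def extract_features(labels: np.ndarray) -> List[FeatureRecord]:
    """One record per labeled object; an empty mask gives an empty list.

    Labels must be consecutive positive integers starting at 1.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels[labels > 0])
    if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
        raise ValueError("labels must be consecutive integers starting at 1")
    records = []
    for prop in measure.regionprops(labels.astype(np.int32)):
        records.append(
            FeatureRecord(
                object_id=int(prop.label),
                area=float(prop.area),
                eccentricity=float(prop.eccentricity),
                solidity=float(prop.solidity),
                extent=float(prop.extent),
                minor_axis_length=float(prop.axis_minor_length),
            )
        )
    return records


@dataclass(frozen=True)
class Prototypes:
    """Per-class mean feature vectors plus the z-normalization statistics of
    the prototype construction set."""

    classes: Tuple[int, ...]
    means: np.ndarray  # (n_classes, n_features)
    mu: np.ndarray  # (n_features,)
    sigma: np.ndarray  # (n_features,), zeros replaced by 1
    feature_names: Tuple[str, ...]


def build_prototypes(
    gt_labels: np.ndarray,
    class_map: Mapping[int, int],
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> Prototypes:
    """Derive per-class prototypes from ground-truth objects of a clean scene."""
    records = extract_features(gt_labels)
    if not records:
        raise ValueError("ground truth contains no objects")
    vectors = np.stack([r.vector(feature_names) for r in records])
    mu = vectors.mean(axis=0)
    sigma = vectors.std(axis=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    by_class: Dict[int, List[np.ndarray]] = {}
    for rec, vec in zip(records, vectors):
        by_class.setdefault(int(class_map[rec.object_id]), []).append(vec)
    classes = tuple(sorted(by_class))
    means = np.stack([np.mean(by_class[k], axis=0) for k in classes])
    return Prototypes(
        classes=classes,
        means=means,
        mu=mu,
        sigma=sigma,
        feature_names=tuple(feature_names),
    )


def classify_objects(
    records: Sequence[FeatureRecord], prototypes: Prototypes
) -> Dict[int, int]:
    """Assign each object to the nearest prototype in z-normalized Euclidean
    distance; ties go to the lower class index."""
    if len(prototypes.classes) < 1:
        raise ValueError("at least one prototype class is required")
    proto_z = (prototypes.means - prototypes.mu) / prototypes.sigma
    assignment: Dict[int, int] = {}
    for rec in records:
        z = (rec.vector(prototypes.feature_names) - prototypes.mu) / prototypes.sigma
        dists = np.linalg.norm(proto_z - z, axis=1)
        # argmin returns the first (lowest class index) on exact ties
        assignment[rec.object_id] = int(prototypes.classes[int(np.argmin(dists))])
    return assignment


def select_target_objects(
    records: Sequence[FeatureRecord], spec: FuzzySpec
) -> List[FeatureRecord]:
    """Objects matching an abstract (fuzzy) description.

    Objects are ranked by the product of their feature memberships.  When
    the target count ``n_c`` is known the top ``n_c`` are retained (ties by
    larger area, then lower object id); otherwise all objects with a
    strictly positive product are retained.
    """
    ranked = rank_by_product(records, spec)
    if spec.n_c is not None:
        chosen = ranked[: spec.n_c]
    else:
        chosen = [(p, i) for p, i in ranked if p > 0]
    return [records[i] for _, i in chosen]
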