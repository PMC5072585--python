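"""Synthetic graded-artifact benchmark: scenes of solid objects with pixel
ground truth, degraded by a grid of shading and Gaussian-noise levels.

A scene is a set of non-overlapping solid shapes (disks, rectangles,
capsules) of known class drawn on a uniform background.  Degradation is
indexed by a shading level ``b`` in ``1..B`` and a noise level ``n`` in
``1..N``; the combined severity is summarized by a scalar artifact level
``A`` in ``[0, 1]`` calibrated so that ``A == 1`` at ``(b, n) == (B, N)``.
The diagonal series ``(b, b + 1)`` for ``b = 1..B`` gives a strictly
increasing artifact ladder with shared ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "DEFAULT_B",
    "DEFAULT_N",
    "DEFAULT_SIGMA_MAX",
    "DEFAULT_SHADING_MAX",
    "SceneSpecError",
    "ObjectSpec",
    "SceneSpec",
    "GroundTruth",
    "BenchmarkSeries",
    "render_scene",
    "shading_field",
    "apply_artifacts",
    "artifact_level",
    "generate_series",
    "default_scene",
]

#: number of shading levels
DEFAULT_B = 13
#: number of noise levels
DEFAULT_N = 14
#: Gaussian noise standard deviation at the highest noise level
DEFAULT_SIGMA_MAX = 0.25
#: multiplicative shading amplitude at the highest shading level
DEFAULT_SHADING_MAX = 0.7

_SHAPES = ("disk", "rectangle", "capsule")


class SceneSpecError(ValueError):
    """Raised for invalid scene specifications (overlap, out-of-frame, ...)."""


@dataclass(frozen=True)
class ObjectSpec:
    """One solid object in a scene.

    Parameters
    ----------
    klass : int
        Object class index in ``1..K``.
    shape : {"disk", "rectangle", "capsule"}
        Geometric primitive.
    size : tuple of float
        ``(radius,)`` for a disk, ``(height, width)`` for a rectangle and
        ``(length, width, angle_deg)`` for a capsule (stadium shape).
    intensity : float
        Fill intensity in ``[0, 1]``.
    position : tuple of float
        ``(row, col)`` center in pixel coordinates.
    """

    klass: int
    shape: str
    size: Tuple[float, ...]
    intensity: float
    position: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.klass < 1:
            raise SceneSpecError(f"object class must be >= 1, got {self.klass}")
        if self.shape not in _SHAPES:
            raise SceneSpecError(f"unknown shape {self.shape!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise SceneSpecError("object intensity must lie in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a clean scene; rendering is deterministic."""

    height: int
    width: int
    objects: Tuple[ObjectSpec, ...] = ()
    background: float = 0.2
    scene_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "objects", tuple(self.objects))
        if self.height < 1 or self.width < 1:
            raise SceneSpecError("image dimensions must be positive")
        if not 0.0 <= self.background <= 1.0:
            raise SceneSpecError("background intensity must lie in [0, 1]")
        if self.scene_id < 1:
            raise SceneSpecError("scene_id must be >= 1")
        classes = sorted({o.klass for o in self.objects})
        if classes and classes != list(range(1, len(classes) + 1)):
            raise SceneSpecError(
                f"object classes must cover 1..K without gaps, got {classes}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Pixel label mask plus the object-id -> class map.

    ``labels`` uses 0 for background and consecutive ids ``1..n`` for
    objects; every id present in the mask has an entry in ``class_map``.
    """

    labels: np.ndarray
    class_map: Dict[int, int]

    @property
    def n_objects(self) -> int:
        return len(self.class_map)

    def class_counts(self) -> Dict[int, int]:
        counts: Dict[int, int] = {}
        for k in self.class_map.values():
            counts[k] = counts.get(k, 0) + 1
        return counts


@dataclass(frozen=True)
class BenchmarkSeries:
    """Diagonal artifact series ``(b, b + 1)`` for ``b = 1..B`` of one scene."""

    spec: SceneSpec
    clean: np.ndarray
    ground_truth: GroundTruth
    b_levels: Tuple[int, ...]
    n_levels: Tuple[int, ...]
    images: Tuple[np.ndarray, ...]
    artifact_levels: Tuple[float, ...]
    a_norm: float
    B: int
    N: int
    sigma_max: float
    shading_max: float

    def __len__(self) -> int:
        return len(self.images)


def _rasterize(obj: ObjectSpec, height: int, width: int) -> np.ndarray:
    rr, cc = np.mgrid[0:height, 0:width].astype(float)
    r0, c0 = obj.position
    if obj.shape == "disk":
        (radius,) = obj.size
        if radius <= 0:
            raise SceneSpecError("disk radius must be positive")
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    if obj.shape == "rectangle":
        h, w = obj.size
        if h <= 0 or w <= 0:
            raise SceneSpecError("rectangle sides must be positive")
        return (np.abs(rr - r0) <= h / 2.0) & (np.abs(cc - c0) <= w / 2.0)
    # capsule: all pixels within width/2 of the central axis segment
    length, w, angle = obj.size
    if w <= 0 or length < w:
        raise SceneSpecError("capsule needs width > 0 and length >= width")
    theta = np.deg2rad(angle)
    dr, dc = np.sin(theta), np.cos(theta)
    half = (length - w) / 2.0
    pr, pc = rr - r0, cc - c0
    t = np.clip(pr * dr + pc * dc, -half, half)
    return np.hypot(pr - t * dr, pc - t * dc) <= w / 2.0


def render_scene(spec: SceneSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Draw the clean scene and its pixel ground truth.

    Raises
    ------
    SceneSpecError
        If any object touches the frame border or two objects overlap.
    """
    image = np.full((spec.height, spec.width), spec.background, dtype=float)
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    class_map: Dict[int, int] = {}
    for i, obj in enumerate(spec.objects, start=1):
        mask = _rasterize(obj, spec.height, spec.width)
        if not mask.any():
            raise SceneSpecError(f"object {i} rasterizes to zero pixels")
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise SceneSpecError(f"object {i} touches the frame border")
        if (labels[mask] != 0).any():
            raise SceneSpecError(f"object {i} overlaps a previous object")
        image[mask] = obj.intensity
        labels[mask] = i
        class_map[i] = obj.klass
    return image, GroundTruth(labels=labels, class_map=class_map)


def shading_field(
    height: int,
    width: int,
    b: int,
    B: int = DEFAULT_B,
    shading_max: float = DEFAULT_SHADING_MAX,
) -> np.ndarray:
    """Multiplicative planar ramp, darkening toward the bottom-right corner.

    Amplitude grows linearly with ``(b - 1) / (B - 1)``; ``b == 1`` gives a
    field of ones.
    """
    amp = shading_max * (b - 1) / (B - 1) if B > 1 else 0.0
    rr, cc = np.mgrid[0:height, 0:width].astype(float)
    grad = np.zeros((height, width)) if height == 1 and width == 1 else (
        rr / max(height - 1, 1) + cc / max(width - 1, 1)
    ) / 2.0
    return 1.0 - amp * grad


def _noise_rng(seed: int, b: int, n: int) -> np.random.Generator:
    # substream per (b, n): adding levels never perturbs existing ones
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(b), int(n)]))


def apply_artifacts(
    image: np.ndarray,
    b: int,
    n: int,
    seed: int,
    B: int = DEFAULT_B,
    N: int = DEFAULT_N,
    sigma_max: float = DEFAULT_SIGMA_MAX,
    shading_max: float = DEFAULT_SHADING_MAX,
) -> np.ndarray:
    """Degrade ``image`` with shading level ``b`` and noise level ``n``.

    Shading multiplies by a planar ramp; noise is additive zero-mean
    Gaussian with ``sigma = sigma_max * (n - 1) / (N - 1)``.  The result is
    clipped to ``[0, 1]`` and is deterministic given ``seed``.
    ``(b, n) == (1, 1)`` returns the input unchanged.
    """
    if not 1 <= b <= B:
        raise ValueError(f"shading level b={b} outside 1..{B}")
    if not 1 <= n <= N:
        raise ValueError(f"noise level n={n} outside 1..{N}")
    out = image * shading_field(image.shape[0], image.shape[1], b, B, shading_max)
    sigma = sigma_max * (n - 1) / (N - 1) if N > 1 else 0.0
    if sigma > 0:
        out = out + _noise_rng(seed, b, n).normal(0.0, sigma, size=image.shape)
    return np.clip(out, 0.0, 1.0)


def artifact_level(
    clean: np.ndarray, degraded: np.ndarray, norm: float = 1.0
) -> float:
    """Scalar artifact level: RMS deviation from the clean image, divided by
    ``norm`` and capped at 1.

    ``norm`` is calibrated per scene (see :func:`generate_series`) so that
    the maximal degradation ``(B, N)`` maps to ``A == 1``.
    """
    if clean.shape != degraded.shape:
        raise ValueError(
            f"shape mismatch: {clean.shape} vs {degraded.shape}"
        )
    rms = float(np.sqrt(np.mean((clean.astype(float) - degraded.astype(float)) ** 2)))
    if norm <= 0:
        raise ValueError("norm must be positive")
    return min(1.0, rms / norm)


def generate_series(
    spec: SceneSpec,
    B: int = DEFAULT_B,
    N: int = DEFAULT_N,
    sigma_max: float = DEFAULT_SIGMA_MAX,
    shading_max: float = DEFAULT_SHADING_MAX,
) -> BenchmarkSeries:
    """Render the scene and emit the diagonal series ``(b, b + 1)``, b = 1..B.

    Each step increases both the shading and the noise level, so the
    artifact levels are strictly increasing (this is asserted numerically).
    The normalization constant is the RMS deviation of the maximal ``(B, N)``
    degradation of this scene.
    """
    if B > N - 1:
        raise ValueError(f"diagonal series needs B <= N - 1, got B={B}, N={N}")
    clean, gt = render_scene(spec)
    worst = apply_artifacts(clean, B, N, spec.seed, B, N, sigma_max, shading_max)
    a_norm = float(np.sqrt(np.mean((clean - worst) ** 2)))
    if a_norm <= 0:
        raise ValueError("scene admits no degradation; cannot calibrate A")
    images = []
    levels = []
    for b in range(1, B + 1):
        img = apply_artifacts(clean, b, b + 1, spec.seed, B, N, sigma_max, shading_max)
        images.append(img)
        levels.append(artifact_level(clean, img, a_norm))
    diffs = np.diff(levels)
    if len(levels) > 1 and not (diffs > 0).all():
        raise RuntimeError(
            "artifact levels not strictly increasing along the diagonal series"
        )
    return BenchmarkSeries(
        spec=spec,
        clean=clean,
        ground_truth=gt,
        b_levels=tuple(range(1, B + 1)),
        n_levels=tuple(range(2, B + 2)),
        images=tuple(images),
        artifact_levels=tuple(levels),
        a_norm=a_norm,
        B=B,
        N=N,
        sigma_max=sigma_max,
        shading_max=shading_max,
    )


def default_scene(seed: int = 0, height: int = 144, width: int = 144) -> SceneSpec:
    """Default benchmark scene: 4 capsules ("set-screw-like": elongated,
    high solidity) of class 1, 2 disks of class 2 and 2 rectangles of
    class 3, all well separated on a dark background."""
    capsule = (24.0, 9.0)
    objs = [
        ObjectSpec(1, "capsule", (*capsule, 0.0), 0.85, (22.0, 40.0)),
        ObjectSpec(1, "capsule", (*capsule, 90.0), 0.80, (44.0, 116.0)),
        ObjectSpec(1, "capsule", (*capsule, 45.0), 0.82, (116.0, 30.0)),
        ObjectSpec(1, "capsule", (*capsule, 135.0), 0.88, (118.0, 112.0)),
        ObjectSpec(2, "disk", (10.0,), 0.75, (50.0, 66.0)),
        ObjectSpec(2, "disk", (7.0,), 0.90, (86.0, 124.0)),
        ObjectSpec(3, "rectangle", (16.0, 16.0), 0.78, (86.0, 70.0)),
        ObjectSpec(3, "rectangle", (10.0, 22.0), 0.86, (20.0, 84.0)),
    ]
    return SceneSpec(
        height=height,
        width=width,
        objects=tuple(objs),
        background=0.2,
        scene_id=1,
        seed=seed,
    )
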