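"""Image, mask and table I/O plus config (de)serialization.

Grayscale PNG/TIFF ingest is rescaled to ``[0, 1]`` by the maximum
representable value of the stored bit depth; color images and unsupported
dtypes are rejected rather than silently converted.  Every table/JSON
output embeds a hash of the producing configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .benchmark import BenchmarkSeries, ObjectSpec, SceneSpec, generate_series
from .evaluation import FuzzySpec

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_table",
    "read_table",
    "write_json",
    "config_hash",
    "scene_spec_to_dict",
    "scene_spec_from_dict",
    "fuzzy_spec_to_dict",
    "fuzzy_spec_from_dict",
    "save_series",
    "load_series",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Unsupported image format, bit depth or color layout."""


def config_hash(config: Dict) -> str:
    """Stable sha256 of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_image(path: PathLike) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as floats in ``[0, 1]``."""
    data = iio.imread(Path(path))
    if data.ndim != 2:
        raise FormatError(f"{path}: expected 2-D grayscale, got shape {data.shape}")
    if data.dtype == np.uint8:
        return data.astype(float) / 255.0
    if data.dtype == np.uint16:
        return data.astype(float) / 65535.0
    if np.issubdtype(data.dtype, np.floating):
        arr = data.astype(float)
        if arr.min() < 0 or arr.max() > 1:
            raise FormatError(f"{path}: float image outside [0, 1]")
        return arr
    raise FormatError(f"{path}: unsupported dtype {data.dtype}")


def write_image(path: PathLike, image: np.ndarray) -> None:
    """Write a float image in ``[0, 1]`` as 16-bit grayscale PNG/TIFF."""
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise FormatError("image values must lie in [0, 1]")
    data = np.round(image * 65535.0).astype(np.uint16)
    iio.imwrite(Path(path), data)


def read_mask(path: PathLike) -> np.ndarray:
    """Read an integer label mask (lossless up to 65535 objects)."""
    data = iio.imread(Path(path))
    if data.ndim != 2:
        raise FormatError(f"{path}: expected 2-D label mask, got shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16, np.int32):
        raise FormatError(f"{path}: unsupported mask dtype {data.dtype}")
    return data.astype(np.int32)


def write_mask(path: PathLike, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 65535:
        raise FormatError("label ids must lie in 0..65535")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def write_table(path: PathLike, table: pd.DataFrame, config: Optional[Dict] = None) -> None:
    """CSV with fixed column order and a leading provenance comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash(config or {})}\n")
        table.to_csv(fh, index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")


def write_json(path: PathLike, payload: Dict, config: Optional[Dict] = None) -> None:
    payload = dict(payload)
    payload.setdefault("config_hash", config_hash(config or {}))
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def scene_spec_to_dict(spec: SceneSpec) -> Dict:
    return {
        "height": spec.height,
        "width": spec.width,
        "background": spec.background,
        "scene_id": spec.scene_id,
        "seed": spec.seed,
        "objects": [
            {
                "klass": o.klass,
                "shape": o.shape,
                "size": list(o.size),
                "intensity": o.intensity,
                "position": list(o.position),
            }
            for o in spec.objects
        ],
    }


def scene_spec_from_dict(d: Dict) -> SceneSpec:
    return SceneSpec(
        height=int(d["height"]),
        width=int(d["width"]),
        background=float(d["background"]),
        scene_id=int(d.get("scene_id", 1)),
        seed=int(d.get("seed", 0)),
        objects=tuple(
            ObjectSpec(
                klass=int(o["klass"]),
                shape=str(o["shape"]),
                size=tuple(float(x) for x in o["size"]),
                intensity=float(o["intensity"]),
                position=tuple(float(x) for x in o["position"]),
            )
            for o in d.get("objects", [])
        ),
    )


def fuzzy_spec_to_dict(spec: FuzzySpec) -> Dict:
    return {
        "feature_edges": {k: list(v) for k, v in spec.feature_edges.items()},
        "count_edges": list(spec.count_edges) if spec.count_edges else None,
        "n_c": spec.n_c,
    }


def fuzzy_spec_from_dict(d: Dict) -> FuzzySpec:
    return FuzzySpec(
        feature_edges={k: tuple(v) for k, v in d["feature_edges"].items()},
        count_edges=tuple(d["count_edges"]) if d.get("count_edges") else None,
        n_c=int(d["n_c"]) if d.get("n_c") is not None else None,
    )


def save_series(series: BenchmarkSeries, out_dir: PathLike) -> None:
    """Write a generated series: images, masks, artifact table and the
    regeneration config (``series.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {
        "spec": scene_spec_to_dict(series.spec),
        "B": series.B,
        "N": series.N,
        "sigma_max": series.sigma_max,
        "shading_max": series.shading_max,
    }
    write_image(out / "clean.png", series.clean)
    write_mask(out / "gt_labels.png", series.ground_truth.labels)
    write_table(
        out / "class_map.csv",
        pd.DataFrame(
            {
                "object_id": list(series.ground_truth.class_map),
                "class": list(series.ground_truth.class_map.values()),
            }
        ),
        cfg,
    )
    rows = []
    for b, n, img, a in zip(
        series.b_levels, series.n_levels, series.images, series.artifact_levels
    ):
        write_image(out / f"image_b{b:02d}_n{n:02d}.png", img)
        rows.append({"scene": series.spec.scene_id, "b": b, "n": n, "A": a})
    write_table(out / "artifacts.csv", pd.DataFrame(rows), cfg)
    write_json(out / "series.json", cfg, cfg)


def load_series(in_dir: PathLike) -> BenchmarkSeries:
    """Regenerate a saved series deterministically from ``series.json``.

    Regeneration (rather than re-reading quantized PNGs) guarantees
    bit-identical float rasters.
    """
    path = Path(in_dir) / "series.json"
    if not path.exists():
        raise FileNotFoundError(f"missing series config: {path}")
    with open(path) as fh:
        cfg = json.load(fh)
    return generate_series(
        scene_spec_from_dict(cfg["spec"]),
        B=int(cfg["B"]),
        N=int(cfg["N"]),
        sigma_max=float(cfg["sigma_max"]),
        shading_max=float(cfg["shading_max"]),
    )
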