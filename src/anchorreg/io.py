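"""Readers and writers for images, point sets, models, transforms and run
configurations.

Images are normalised to float in [0, 1] on read (8/16-bit integer or float
TIFF and PNG; RGB input is converted to luminance).  Writes default to
16-bit TIFF.  Point sets round-trip through CSV (header ``x,y`` with an
optional ``score`` column, repr-precision floats) or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .estimation import LmedsConfig
from .extraction import DetectionConfig
from .transforms import AffineParams, TransformMatrix
from .validation import HomographyMagnitude, MetricConfig, SweepConfig
from .anchor_models import AnchorModel, UnitCellTemplate

__all__ = [
    "read_image",
    "write_image",
    "read_points",
    "write_points",
    "read_model",
    "write_model",
    "read_transform",
    "write_transform",
    "load_run_config",
    "RunConfig",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG image as a float array in [0, 1]."""
    p = Path(path)
    if not p.exists():
        raise InvalidParameterError(f"image file not found: {p}")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        a = tifffile.imread(p)
    elif suffix == ".png":
        import imageio.v3 as iio

        a = iio.imread(p)
    else:
        raise InvalidParameterError(f"unsupported image format {suffix!r}: {p}")
    a = np.asarray(a)
    if a.ndim == 3:
        if a.shape[2] == 4:
            a = a[..., :3]
        a = a.astype(float) @ _LUMA
        scale = 255.0 if a.max() > 1.0 else 1.0
        return np.clip(a / scale, 0.0, 1.0)
    if a.dtype == np.uint8:
        return a.astype(float) / 255.0
    if a.dtype == np.uint16:
        return a.astype(float) / 65535.0
    return np.clip(a.astype(float), 0.0, 1.0)


def write_image(img, path, dtype: str = "uint16") -> None:
    """Write a float [0, 1] image; 16-bit TIFF by default, PNG supported."""
    a = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    p = Path(path)
    suffix = p.suffix.lower()
    if dtype == "uint16":
        q = np.round(a * 65535.0).astype(np.uint16)
    elif dtype == "uint8":
        q = np.round(a * 255.0).astype(np.uint8)
    else:
        raise InvalidParameterError(f"unsupported dtype {dtype!r}")
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(p, q)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(p, q)
    else:
        raise InvalidParameterError(f"unsupported image format {suffix!r}: {p}")


def read_points(path) -> np.ndarray:
    """Read an (N, 2) point set from CSV (header x,y[,score]) or JSON."""
    p = Path(path)
    if not p.exists():
        raise InvalidParameterError(f"point file not found: {p}")
    if p.suffix.lower() == ".json":
        data = json.loads(p.read_text())
        pts = data["points"] if isinstance(data, dict) else data
        return np.asarray(pts, dtype=float).reshape(-1, 2)
    text = p.read_text().strip()
    if not text:
        return np.empty((0, 2))
    lines = text.splitlines()
    header = [h.strip() for h in lines[0].split(",")]
    if "x" not in header or "y" not in header:
        raise InvalidParameterError(f"{p}: line 1: expected header with x,y columns")
    xi, yi = header.index("x"), header.index("y")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(",")
        try:
            out.append((float(fields[xi]), float(fields[yi])))
        except (ValueError, IndexError) as err:
            raise InvalidParameterError(f"{p}: line {lineno}: {err}") from err
    return np.asarray(out, dtype=float).reshape(-1, 2)


def write_points(pts, path, scores=None) -> None:
    """Write an (N, 2) point set as CSV with header x,y[,score]."""
    p = Path(path)
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps({"points": pts.tolist()}))
        return
    # repr-precision floats for a bit-exact round trip
    cols = [pts[:, 0], pts[:, 1]]
    header = "x,y"
    if scores is not None:
        cols.append(np.asarray(scores, dtype=float))
        header += ",score"
    lines = [header] + [
        ",".join(repr(float(c[i])) for c in cols) for i in range(len(pts))
    ]
    p.write_text("\n".join(lines) + "\n")


def _read_json(path) -> dict:
    p = Path(path)
    if not p.exists():
        raise InvalidParameterError(f"file not found: {p}")
    return json.loads(p.read_text())


def read_model(path) -> AnchorModel:
    return AnchorModel.from_dict(_read_json(path))


def write_model(model: AnchorModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_template(path) -> UnitCellTemplate:
    return UnitCellTemplate.from_dict(_read_json(path))


def write_template(template: UnitCellTemplate, path) -> None:
    Path(path).write_text(json.dumps(template.to_dict(), indent=1))


def read_transform(path) -> TransformMatrix:
    return TransformMatrix.from_dict(_read_json(path))


def write_transform(T: TransformMatrix, path) -> None:
    Path(path).write_text(T.to_json())


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Nested configuration for CLI runs; unknown keys are rejected."""

    affine: AffineParams = dataclasses.field(default_factory=AffineParams)
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)
    lmeds: LmedsConfig = dataclasses.field(default_factory=LmedsConfig)
    metric: MetricConfig = dataclasses.field(default_factory=MetricConfig)
    gate: float | None = None
    vote_radius: float | None = None
    grid_steps: int = 50
    seed: int = 0


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidParameterError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(names)}"
        )
    return cls(**data)


def load_run_config(path_or_dict) -> RunConfig:
    """Load a RunConfig from YAML/JSON (strict: unknown keys are errors)."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        import yaml

        p = Path(path_or_dict)
        if not p.exists():
            raise InvalidParameterError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
    nested = {
        "affine": AffineParams,
        "detection": DetectionConfig,
        "lmeds": LmedsConfig,
        "metric": MetricConfig,
    }
    kwargs = {}
    for key, cls in nested.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key) or {}, key)
    return _build(RunConfig, {**data, **kwargs}, "run config")


def load_sweep_config(path_or_dict) -> SweepConfig:
    """Load a SweepConfig from YAML/JSON (strict)."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        import yaml

        p = Path(path_or_dict)
        if not p.exists():
            raise InvalidParameterError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
    if "magnitude" in data:
        data["magnitude"] = _build(
            HomographyMagnitude, data.pop("magnitude") or {}, "magnitude"
        )
    if "lmeds" in data:
        data["lmeds"] = _build(LmedsConfig, data.pop("lmeds") or {}, "lmeds")
    if "noise_stds" in data:
        data["noise_stds"] = tuple(data["noise_stds"])
    if "point_counts" in data:
        data["point_counts"] = tuple(data["point_counts"])
    return _build(SweepConfig, data, "sweep config")
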