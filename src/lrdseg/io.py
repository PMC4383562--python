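"""Image/mask readers and writers, run configuration and result export.

All intensities are put on a 0-255 working scale on ingestion: integer
images by their nominal dtype range, floating images by min-max rescale
(recorded in the log). The 0-255 scale matters because the default
length weight ``beta = 0.003 * 255 * 255`` presumes it.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .evolve2 import SegmentationResult
from .exceptions import InvalidInputError, InvalidParameterError
from .model import ModelParams

logger = logging.getLogger(__name__)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image onto the 0-255 working scale."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as err:  # imageio raises various backend errors
        raise InvalidInputError(f"cannot read image {path}: {err}") from err
    source_dtype = arr.dtype
    if arr.ndim == 3:
        logger.warning("%s is multi-channel; averaging channels to luminance", path)
        arr = arr.mean(axis=-1)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError(f"{path}: expected a non-empty 2-D image")
    if np.issubdtype(source_dtype, np.integer):
        info = np.iinfo(source_dtype)
        scale = 255.0 / max(info.max, 1)
        return arr.astype(float) * scale
    arr = arr.astype(float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{path}: non-finite pixel values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise InvalidInputError(f"{path}: constant image has no contrast")
    logger.info("rescaling float image %s: [%g, %g] -> [0, 255]", path, lo, hi)
    return (arr - lo) * (255.0 / (hi - lo))


def read_labels(path) -> np.ndarray:
    """Read a label/mask image without intensity rescaling."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int32)


def parse_init_region(spec: str, shape) -> np.ndarray:
    """Parse an initialization region: mask path, box or circle.

    Accepted forms (0-based row/col coordinates, half-open boxes):
    ``box r0,c0,r1,c1``; ``circle r,c,radius``; any other string is
    treated as a mask-image path (non-zero pixels seed the region).
    """
    h, w = shape
    parts = spec.split()
    if parts and parts[0] in {"box", "circle"}:
        try:
            vals = [float(v) for v in " ".join(parts[1:]).replace(",", " ").split()]
        except ValueError as err:
            raise InvalidParameterError(f"bad init region {spec!r}") from err
        if parts[0] == "box" and len(vals) == 4:
            r0, c0, r1, c1 = vals
            rows, cols = np.mgrid[0:h, 0:w]
            return (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)
        if parts[0] == "circle" and len(vals) == 3:
            r, c, radius = vals
            rows, cols = np.mgrid[0:h, 0:w]
            return np.hypot(rows - r, cols - c) < radius
        raise InvalidParameterError(f"bad init region {spec!r}")
    mask = read_labels(spec)
    if mask.shape != tuple(shape):
        raise InvalidInputError(
            f"init mask shape {mask.shape} does not match image shape {tuple(shape)}"
        )
    return mask > 0


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


@dataclass
class RunConfig:
    """A full segmentation run: model parameters plus I/O and init specs."""

    input: str = ""
    output: str = "out"
    init: str = ""
    init2: str = ""
    params: ModelParams = dataclasses.field(default_factory=ModelParams)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {"input", "output", "init", "init2"}
        top = {k: data.pop(k) for k in list(data) if k in known}
        param_data = {k: data.pop(k) for k in list(data) if k in _PARAM_FIELDS}
        if data:
            raise InvalidParameterError(f"unknown config keys: {sorted(data)}")
        return cls(params=ModelParams(**param_data), **top)

    def to_dict(self) -> dict:
        out = {
            "input": self.input,
            "output": self.output,
            "init": self.init,
            "init2": self.init2,
        }
        out.update(dataclasses.asdict(self.params))
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidParameterError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _to_uint16(field: np.ndarray) -> np.ndarray:
    scaled = np.clip(field, 0.0, 255.0) * (65535.0 / 255.0)
    return np.round(scaled).astype(np.uint16)


def write_result(result: SegmentationResult, out_dir, params: ModelParams | None = None) -> dict:
    """Write a segmentation result; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}
    iio.imwrite(out / "labels.png", result.labels.astype(np.uint8))
    files["labels"] = "labels.png"
    phi_files = []
    for i, phi in enumerate(result.phis, start=1):
        name = f"phi_{i}.tif"
        tifffile.imwrite(out / name, phi.astype(np.float32))
        phi_files.append(name)
    files["phis"] = phi_files
    tifffile.imwrite(out / "bias.tif", result.bias.b.astype(np.float32))
    files["bias"] = "bias.tif"
    tifffile.imwrite(out / "difference.tif", result.bias.d.astype(np.float32))
    files["difference"] = "difference.tif"
    tifffile.imwrite(out / "corrected.tif", _to_uint16(result.corrected))
    files["corrected"] = "corrected.tif"
    with open(out / "energy.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "energy"])
        for i, e in enumerate(result.energy_trace, start=1):
            writer.writerow([i, repr(e)])
    files["energy"] = "energy.csv"

    manifest = {
        "files": files,
        "class_means": [float(c) for c in result.bias.c],
        "iterations_run": result.iterations_run,
        "converged": result.converged,
        "params": dataclasses.asdict(params) if params is not None else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_phantom(phantom, out_dir) -> dict:
    """Write a generated phantom: image, labels, bias and JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "image.tif", _to_uint16(phantom.image))
    iio.imwrite(out / "labels.png", phantom.true_labels.astype(np.uint8))
    tifffile.imwrite(out / "bias.tif", phantom.true_bias.astype(np.float32))
    sidecar = dataclasses.asdict(phantom.spec)
    sidecar["clip_fraction"] = phantom.clip_fraction
    with open(out / "spec.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar
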