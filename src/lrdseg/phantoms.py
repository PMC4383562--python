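"""Synthetic phantoms with known class map, bias field and noise.

Phantoms follow the forward model ``I = b * J + n`` (two-phase) or
``I = b * J + d + n`` with ``d`` arising only from deliberate artifacts:
a piecewise-constant class image ``J`` (values ``class_means``), a smooth
slowly varying multiplicative bias ``b`` (mean-normalized to 1, so the
class means keep their stated scale) and additive Gaussian noise.

Geometries emulate the kinds of test images used for this family of
models: a T-shaped object, a star with satellite disks, plain disks, and
a "brain-like" arrangement of three nested wavy regions exercising the
three-phase coupling. The bias families (linear ramp, Gaussian bump,
low-order polynomial) are representative smooth fields, not replicas of
any specific scanner profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidParameterError

GEOMETRIES = ("tshape", "star", "disks", "brainlike")
BIAS_KINDS = ("identity", "linear_ramp", "gaussian_bump", "polynomial")


@dataclass(frozen=True)
class PhantomSpec:
    name: str = "phantom"
    shape: tuple[int, int] = (128, 128)
    n_classes: int = 2
    class_means: tuple[float, ...] = (60.0, 170.0)
    geometry: str = "tshape"
    bias_kind: str = "identity"
    bias_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (2, 3):
            raise InvalidParameterError("n_classes must be 2 or 3")
        if len(self.class_means) != self.n_classes:
            raise InvalidParameterError("class_means length must equal n_classes")
        if len(set(self.class_means)) != self.n_classes:
            raise InvalidParameterError("class_means must be pairwise distinct")
        if self.geometry not in GEOMETRIES:
            raise InvalidParameterError(f"unknown geometry {self.geometry!r}")
        if self.bias_kind not in BIAS_KINDS:
            raise InvalidParameterError(f"unknown bias_kind {self.bias_kind!r}")
        lo, hi = self.bias_range
        if lo <= 0 or hi < lo:
            raise InvalidParameterError("bias_range must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    true_labels: np.ndarray
    true_bias: np.ndarray
    true_means: np.ndarray
    clip_fraction: float
    spec: PhantomSpec


def _grids(shape):
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    return rows, cols


def _tshape_labels(shape) -> np.ndarray:
    h, w = shape
    rows, cols = _grids(shape)
    bar = (rows >= 0.15 * h) & (rows < 0.35 * h) & (cols >= 0.12 * w) & (cols < 0.88 * w)
    stem = (rows >= 0.35 * h) & (rows < 0.85 * h) & (cols >= 0.40 * w) & (cols < 0.60 * w)
    labels = np.ones(shape, dtype=np.int32)
    labels[bar | stem] = 2
    return labels


def _star_labels(shape) -> np.ndarray:
    h, w = shape
    rows, cols = _grids(shape)
    m = min(h, w)
    cy, cx = 0.52 * h, 0.55 * w
    dy, dx = rows - cy, cols - cx
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    star = r < 0.22 * m * (1.0 + 0.35 * np.cos(5.0 * theta))
    disk1 = np.hypot(rows - 0.22 * h, cols - 0.22 * w) < 0.07 * m
    disk2 = np.hypot(rows - 0.80 * h, cols - 0.22 * w) < 0.06 * m
    labels = np.ones(shape, dtype=np.int32)
    labels[star | disk1 | disk2] = 2
    return labels


def _disks_labels(shape) -> np.ndarray:
    h, w = shape
    rows, cols = _grids(shape)
    m = min(h, w)
    centers = [(0.3, 0.3, 0.14), (0.35, 0.72, 0.10), (0.72, 0.5, 0.16)]
    obj = np.zeros(shape, dtype=bool)
    for fy, fx, fr in centers:
        obj |= np.hypot(rows - fy * h, cols - fx * w) < fr * m
    labels = np.ones(shape, dtype=np.int32)
    labels[obj] = 2
    return labels


def _brainlike_labels(shape) -> np.ndarray:
    h, w = shape
    rows, cols = _grids(shape)
    m = min(h, w)
    cy, cx = 0.5 * h, 0.5 * w
    dy, dx = rows - cy, cols - cx
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    outer = r < 0.37 * m * (1.0 + 0.08 * np.sin(3.0 * theta) + 0.05 * np.cos(5.0 * theta))
    inner = r < 0.18 * m * (1.0 + 0.10 * np.cos(2.0 * theta) - 0.06 * np.sin(4.0 * theta))
    labels = np.ones(shape, dtype=np.int32)
    labels[outer] = 2
    labels[inner] = 3
    return labels


_GEOMETRY_BUILDERS = {
    "tshape": _tshape_labels,
    "star": _star_labels,
    "disks": _disks_labels,
    "brainlike": _brainlike_labels,
}


def _bias_profile(kind: str, shape) -> np.ndarray:
    """Raw smooth profile in [0, 1] before range mapping."""
    h, w = shape
    rows, cols = _grids(shape)
    if kind == "identity":
        return np.zeros(shape, dtype=float)
    if kind == "linear_ramp":
        return 0.5 * (rows / (h - 1) + cols / (w - 1))
    if kind == "gaussian_bump":
        s = 0.35 * min(h, w)
        f = np.exp(-((rows - 0.4 * h) ** 2 + (cols - 0.6 * w) ** 2) / (2.0 * s**2))
    elif kind == "polynomial":
        x = cols / (w - 1)
        y = rows / (h - 1)
        f = 0.2 + 0.8 * x + 0.5 * y - 0.6 * x**2 - 0.3 * y**2 + 0.4 * x * y
    else:  # pragma: no cover - guarded by PhantomSpec validation
        raise InvalidParameterError(f"unknown bias_kind {kind!r}")
    return (f - f.min()) / (f.max() - f.min())


def make_bias(kind: str, shape, bias_range) -> np.ndarray:
    """Smooth bias field with max/min ratio ``bias_range[1]/bias_range[0]``,
    mean-normalized to 1 (the model only identifies b up to scale)."""
    lo, hi = bias_range
    b = lo + (hi - lo) * _bias_profile(kind, shape)
    return b / b.mean()


def generate(spec: PhantomSpec) -> Phantom:
    """Deterministically generate a phantom from its spec."""
    labels = _GEOMETRY_BUILDERS[spec.geometry](spec.shape)
    means = np.asarray(spec.class_means, dtype=float)
    J = means[labels - 1]
    bias = make_bias(spec.bias_kind, spec.shape, spec.bias_range)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd > 0 else 0.0
    raw = bias * J + noise
    image = np.clip(raw, 0.0, 255.0)
    clip_fraction = float(np.mean(raw != image))
    if clip_fraction > 0:
        warnings.warn(
            f"phantom {spec.name!r}: {clip_fraction:.2%} of pixels clipped to [0, 255]",
            stacklevel=2,
        )
    return Phantom(
        image=image,
        true_labels=labels,
        true_bias=bias,
        true_means=means,
        clip_fraction=clip_fraction,
        spec=spec,
    )


def count_intensity_modes(
    values: np.ndarray, bin_width: float = 2.0, min_mass: float = 0.005
) -> int:
    """Number of modes of a quantized intensity histogram.

    Counts peaks of the histogram (bins of ``bin_width`` over [0, 255])
    whose prominence exceeds ``min_mass`` of the total pixel count. A
    bias-free piecewise-constant image shows one mode per class; a
    multiplicative bias smears each class across many bins.
    """
    from scipy.signal import find_peaks

    vals = np.asarray(values, dtype=float).ravel()
    bins = np.arange(0.0, 255.0 + 2 * bin_width, bin_width)
    hist, _ = np.histogram(vals, bins=bins)
    padded = np.concatenate([[0], hist, [0]])
    peaks, _ = find_peaks(padded, prominence=min_mass * vals.size)
    return int(len(peaks))


def default_suite() -> list[PhantomSpec]:
    """The named phantom specs used throughout the tests and examples."""
    return [
        PhantomSpec(
            name="tshape-clean",
            geometry="tshape",
            bias_kind="identity",
            noise_sd=0.0,
            seed=101,
        ),
        PhantomSpec(
            name="tshape-bias",
            geometry="tshape",
            bias_kind="linear_ramp",
            bias_range=(0.8, 1.2),
            noise_sd=5.0,
            seed=102,
        ),
        PhantomSpec(
            name="star-bias",
            geometry="star",
            class_means=(50.0, 180.0),
            bias_kind="gaussian_bump",
            bias_range=(0.8, 1.3),
            noise_sd=5.0,
            seed=103,
        ),
        PhantomSpec(
            name="disks-bias",
            geometry="disks",
            bias_kind="polynomial",
            bias_range=(0.8, 1.2),
            noise_sd=5.0,
            seed=104,
        ),
        PhantomSpec(
            name="brainlike-clean",
            n_classes=3,
            class_means=(40.0, 110.0, 180.0),
            geometry="brainlike",
            bias_kind="identity",
            noise_sd=0.0,
            seed=105,
        ),
        PhantomSpec(
            name="brainlike-bias",
            n_classes=3,
            class_means=(40.0, 110.0, 180.0),
            geometry="brainlike",
            bias_kind="gaussian_bump",
            bias_range=(0.7, 1.3),
            noise_sd=5.0,
            seed=106,
        ),
        PhantomSpec(
            name="brainlike-ramp",
            n_classes=3,
            class_means=(40.0, 110.0, 180.0),
            geometry="brainlike",
            bias_kind="linear_ramp",
            bias_range=(0.7, 1.3),
            noise_sd=5.0,
            seed=107,
        ),
    ]


def get_spec(name: str) -> PhantomSpec:
    """Look up a suite spec by name."""
    for spec in default_suite():
        if spec.name == name:
            return spec
    raise KeyError(f"no phantom preset named {name!r}")


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    return replace(spec, seed=int(seed))
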