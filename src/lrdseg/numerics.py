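"""Shared numerical primitives for level-set bias-correction models.

This module fixes the discrete conventions used everywhere else in the
package:

* a truncated, unit-sum Gaussian window of size ``(4k+1) x (4k+1)`` where
  ``k`` is the greatest integer strictly smaller than the standard
  deviation ``sigma``;
* the arctangent-smoothed Heaviside ``H_eps`` and its derivative, the
  smoothed Dirac delta ``delta_eps``;
* central-difference gradients, a 5-point Laplacian and the
  mean-curvature operator ``div(grad(phi)/|grad(phi)|)``, all on a
  unit-spaced (row, col) grid with replicate-edge (Neumann) boundary
  handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import InvalidInputError, InvalidParameterError

#: Additive stabilizer under the gradient-magnitude square root; keeps the
#: normalized gradient finite in flat regions of phi.
GRAD_STABILIZER = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """A truncated, normalized Gaussian window.

    Attributes
    ----------
    sigma : float
        Standard deviation of the Gaussian, in pixels.
    half_width : int
        ``k``, the greatest integer strictly smaller than ``sigma``
        (clamped to at least 1).
    window_size : int
        ``4*k + 1`` (odd).
    weights : ndarray
        The 2-D window, non-negative, radially symmetric, summing to 1.
    weights_1d : ndarray
        The normalized 1-D Gaussian factor; ``weights`` is its outer
        product with itself, so the convolution is separable.
    """

    sigma: float
    half_width: int
    window_size: int
    weights: np.ndarray = field(repr=False)
    weights_1d: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SmoothedStepSpec:
    """Smoothing width ``epsilon`` of the regularized Heaviside/Dirac pair."""

    epsilon: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.epsilon) and self.epsilon > 0):
            raise InvalidParameterError(f"epsilon must be positive, got {self.epsilon}")


def build_kernel(sigma: float) -> KernelSpec:
    """Build the truncated Gaussian window for a given ``sigma``.

    The window half-extent is ``2k`` with ``k`` the greatest integer
    strictly smaller than ``sigma`` (``sigma=3 -> 9x9`` window); the
    truncated profile is renormalized to unit sum so that convolving a
    constant field returns the same constant.
    """
    sigma = float(sigma)
    if not (np.isfinite(sigma) and sigma > 0):
        raise InvalidParameterError(f"sigma must be a positive real, got {sigma}")
    k = max(int(np.ceil(sigma)) - 1, 1)
    half = 2 * k
    offsets = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(offsets**2) / (2.0 * sigma**2))
    g /= g.sum()
    weights = np.outer(g, g)
    return KernelSpec(
        sigma=sigma,
        half_width=k,
        window_size=4 * k + 1,
        weights=weights,
        weights_1d=g,
    )


def local_convolve(field_arr: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Convolve ``field_arr`` with the kernel window, replicating edges.

    Replicate-edge padding is the discrete counterpart of the Neumann
    boundary condition used by the level-set evolution. The separable
    implementation is numerically identical (to round-off) to a direct
    windowed sum because the normalized square-window Gaussian factors
    exactly into an outer product.
    """
    arr = np.asarray(field_arr, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D field, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("field contains non-finite values")
    out = ndimage.convolve1d(arr, kernel.weights_1d, axis=0, mode="nearest")
    out = ndimage.convolve1d(out, kernel.weights_1d, axis=1, mode="nearest")
    return out


def heaviside(s: np.ndarray, spec: SmoothedStepSpec) -> np.ndarray:
    """Smoothed Heaviside ``H_eps(s) = (1 + (2/pi) atan(s/eps)) / 2``."""
    s = np.asarray(s, dtype=float)
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(s / spec.epsilon))


def dirac(s: np.ndarray, spec: SmoothedStepSpec) -> np.ndarray:
    """Smoothed Dirac delta ``delta_eps(s) = eps / (pi (eps^2 + s^2))``."""
    s = np.asarray(s, dtype=float)
    eps = spec.epsilon
    return (eps / np.pi) / (eps**2 + s**2)


def _edge_pad(f: np.ndarray) -> np.ndarray:
    return np.pad(f, 1, mode="edge")


def central_gradient(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient ``(d/drow, d/dcol)`` with replicated edges."""
    fp = _edge_pad(np.asarray(f, dtype=float))
    gy = 0.5 * (fp[2:, 1:-1] - fp[:-2, 1:-1])
    gx = 0.5 * (fp[1:-1, 2:] - fp[1:-1, :-2])
    return gy, gx


def curvature(phi: np.ndarray) -> np.ndarray:
    """Mean curvature ``div(grad(phi)/|grad(phi)|)`` of the level lines.

    The gradient magnitude is stabilized as
    ``sqrt(phi_x^2 + phi_y^2 + GRAD_STABILIZER)`` so flat regions return 0
    instead of 0/0.
    """
    phi = np.asarray(phi, dtype=float)
    gy, gx = central_gradient(phi)
    mag = np.sqrt(gx**2 + gy**2 + GRAD_STABILIZER)
    ny = gy / mag
    nx = gx / mag
    dny_dy, _ = central_gradient(ny)
    _, dnx_dx = central_gradient(nx)
    return dny_dy + dnx_dx


def laplacian(phi: np.ndarray) -> np.ndarray:
    """5-point Laplacian with replicated (Neumann) edges."""
    phi = np.asarray(phi, dtype=float)
    fp = _edge_pad(phi)
    return fp[2:, 1:-1] + fp[:-2, 1:-1] + fp[1:-1, 2:] + fp[1:-1, :-2] - 4.0 * phi
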