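"""Three-phase segmentation driver with two coupled level-set functions.

Memberships are built from two level sets:

    u1 = H(phi1) H(phi2),  u2 = H(phi1) (1 - H(phi2)),  u3 = 1 - H(phi1)

so u3 absorbs the fourth sign combination and the partition always sums
to 1. The coupled gradient flows are

    dphi1/dt = delta(phi1) ((f2 - f1) H(phi2) + f3 - f2) + regularization
    dphi2/dt = delta(phi2) (f2 - f1) H(phi1)             + regularization

the exact negative functional derivatives of the three-class data term.
phi1 is stepped before phi2 (Gauss-Seidel); the fit maps f_i depend only
on (b, c, d) and are frozen within an outer iteration.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import DivergenceError
from .evolve2 import CONV_CHECK_EVERY, SegmentationResult, init_level_set
from .model import (
    BiasModel,
    ModelParams,
    _as_image,
    corrected_image,
    fit_maps,
    normalize_bias,
    refit_on_partition,
    total_energy,
    update_b,
    update_c,
    update_d,
)
from .numerics import (
    SmoothedStepSpec,
    build_kernel,
    curvature,
    dirac,
    heaviside,
    laplacian,
)

logger = logging.getLogger(__name__)


def memberships_3p(phi1, phi2, spec: SmoothedStepSpec) -> list[np.ndarray]:
    """Three-class memberships from two level sets; sums to 1 identically."""
    h1 = heaviside(np.asarray(phi1, dtype=float), spec)
    h2 = heaviside(np.asarray(phi2, dtype=float), spec)
    return [h1 * h2, h1 * (1.0 - h2), 1.0 - h1]


def _reg_force(phi: np.ndarray, params: ModelParams, delta: np.ndarray) -> np.ndarray:
    kappa = curvature(phi)
    return params.alpha * (laplacian(phi) - kappa) + params.beta * delta * kappa


def _step_phi1(phi1, phi2, f, params, spec):
    delta1 = dirac(phi1, spec)
    h2 = heaviside(phi2, spec)
    data = delta1 * ((f[1] - f[0]) * h2 + f[2] - f[1])
    return phi1 + params.dt * (data + _reg_force(phi1, params, delta1))


def _step_phi2(phi1, phi2, f, params, spec):
    delta2 = dirac(phi2, spec)
    h1 = heaviside(phi1, spec)
    data = delta2 * (f[1] - f[0]) * h1
    return phi2 + params.dt * (data + _reg_force(phi2, params, delta2))


def evolve_step_3p(image, bias: BiasModel, phi1, phi2, params: ModelParams, kernel):
    """One coupled explicit step; phi1 is updated first, then phi2."""
    f = fit_maps(image, bias, kernel)
    spec = params.step_spec
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    phi1_new = _step_phi1(phi1, phi2, f, params, spec)
    phi2_new = _step_phi2(phi1_new, phi2, f, params, spec)
    if not (np.all(np.isfinite(phi1_new)) and np.all(np.isfinite(phi2_new))):
        raise DivergenceError(
            "level sets diverged (non-finite phi); try a smaller time step dt"
        )
    return phi1_new, phi2_new


def labels_3p(phi1, phi2, spec: SmoothedStepSpec) -> np.ndarray:
    """Label map 1..3 by largest membership."""
    u = memberships_3p(phi1, phi2, spec)
    return (np.argmax(np.stack(u), axis=0) + 1).astype(np.int32)


def segment_three_phase(
    image, init_mask1, init_mask2, params: ModelParams | None = None
) -> SegmentationResult:
    """Three-class alternating-minimization segmentation.

    ``init_mask1`` and ``init_mask2`` seed the two level sets; by the
    membership construction the region outside the first seed converges
    to class 3, the region inside both seeds to class 1 and the remainder
    to class 2 (up to relabeling driven by the data).
    """
    if params is None:
        params = ModelParams(n_classes=3, max_iters=400)
    I = _as_image(image)
    kernel = build_kernel(params.sigma)
    spec = params.step_spec

    c0 = params.resolved_c0(2)
    phi1 = init_level_set(I.shape, init_mask1, c0, seed_positive=params.seed_positive)
    phi2 = init_level_set(I.shape, init_mask2, c0, seed_positive=params.seed_positive)
    bias = BiasModel.initial(I.shape, 3)
    u = memberships_3p(phi1, phi2, spec)
    bias = bias.with_(c=update_c(I, bias, u, kernel))

    energy_trace: list[float] = []
    labels_prev = labels_3p(phi1, phi2, spec)
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        u = memberships_3p(phi1, phi2, spec)
        bias = bias.with_(c=update_c(I, bias, u, kernel, prev=bias.c))
        bias = bias.with_(b=update_b(I, bias, u, kernel))
        if not params.baseline_li:
            bias = bias.with_(d=update_d(I, bias, u, kernel))
        f = fit_maps(I, bias, kernel)
        try:
            for _ in range(params.inner_steps):
                phi1_new = _step_phi1(phi1, phi2, f, params, spec)
                phi2_new = _step_phi2(phi1_new, phi2, f, params, spec)
                if not (
                    np.all(np.isfinite(phi1_new)) and np.all(np.isfinite(phi2_new))
                ):
                    raise DivergenceError(
                        "level sets diverged (non-finite phi); try a smaller dt"
                    )
                phi1, phi2 = phi1_new, phi2_new
        except DivergenceError as err:
            raise DivergenceError(f"{err} (outer iteration {it})") from err
        energy_trace.append(total_energy(I, bias, [phi1, phi2], params, kernel))
        logger.debug("iter %d energy %.6g", it, energy_trace[-1])
        if it % CONV_CHECK_EVERY == 0:
            lab = labels_3p(phi1, phi2, spec)
            changed = float(np.mean(lab != labels_prev))
            labels_prev = lab
            if changed < params.conv_tol:
                converged = True
                break

    labels = labels_3p(phi1, phi2, spec)
    if params.max_iters > 0 and len(np.unique(labels)) == 3:
        bias = refit_on_partition(I, labels, 3, params, kernel, fallback_c=bias.c)
    bias = normalize_bias(bias)
    return SegmentationResult(
        labels=labels,
        phis=[phi1, phi2],
        bias=bias,
        corrected=corrected_image(I, bias),
        energy_trace=energy_trace,
        iterations_run=it,
        converged=converged,
    )
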