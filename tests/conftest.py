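"""Shared fixtures: phantoms, seed regions and cached segmentation runs.

The full-size recovery runs are expensive (seconds each), so every run
that more than one test inspects is computed once per session.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lrdseg import ModelParams, segment_three_phase, segment_two_phase
from lrdseg.phantoms import generate, get_spec


def circle_mask(shape, row, col, radius):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rows - row, cols - col) < radius


def box_mask(shape, r0, c0, r1, c1):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)


@pytest.fixture(scope="session")
def tshape_bias_phantom():
    return generate(get_spec("tshape-bias"))


@pytest.fixture(scope="session")
def tshape_clean_phantom():
    return generate(get_spec("tshape-clean"))


@pytest.fixture(scope="session")
def brainlike_clean_phantom():
    return generate(get_spec("brainlike-clean"))


@pytest.fixture(scope="session")
def brainlike_bias_phantom():
    return generate(get_spec("brainlike-bias"))


@pytest.fixture(scope="session")
def brainlike_ramp_phantom():
    return generate(get_spec("brainlike-ramp"))


@pytest.fixture(scope="session")
def two_phase_runs(tshape_bias_phantom):
    """The default two-class recovery run under two different inits."""
    ph = tshape_bias_phantom
    params = ModelParams(max_iters=200)
    init_a = circle_mask(ph.image.shape, 40, 55, 12)  # inside the object
    init_b = box_mask(ph.image.shape, 55, 20, 105, 70)  # straddles both classes
    return {
        "phantom": ph,
        "a": segment_two_phase(ph.image, init_a, params),
        "b": segment_two_phase(ph.image, init_b, params),
    }


@pytest.fixture(scope="session")
def three_phase_seeds():
    shape = (128, 128)
    return circle_mask(shape, 64, 64, 42), circle_mask(shape, 60, 68, 16)


@pytest.fixture(scope="session")
def three_phase_clean_run(brainlike_clean_phantom, three_phase_seeds):
    m1, m2 = three_phase_seeds
    params = ModelParams(n_classes=3, max_iters=400)
    return segment_three_phase(brainlike_clean_phantom.image, m1, m2, params)


@pytest.fixture(scope="session")
def three_phase_bias_run(brainlike_bias_phantom, three_phase_seeds):
    m1, m2 = three_phase_seeds
    params = ModelParams(n_classes=3, max_iters=400)
    return segment_three_phase(brainlike_bias_phantom.image, m1, m2, params)


@pytest.fixture(scope="session")
def three_phase_ramp_run(brainlike_ramp_phantom, three_phase_seeds):
    m1, m2 = three_phase_seeds
    params = ModelParams(n_classes=3, max_iters=400)
    return segment_three_phase(brainlike_ramp_phantom.image, m1, m2, params)


@pytest.fixture(scope="session")
def noise_free_bias_run():
    """Noise-free biased two-class phantom plus its segmentation."""
    spec = dataclasses.replace(
        get_spec("tshape-bias"), noise_sd=0.0, name="tshape-bias-noisefree"
    )
    ph = generate(spec)
    params = ModelParams(max_iters=200)
    result = segment_two_phase(ph.image, circle_mask(ph.image.shape, 40, 55, 12), params)
    return {"phantom": ph, "result": result}


def random_instance(rng, shape=(16, 16), n_classes=2, smooth_fields=True):
    """A random model instance consistent with the slow-variation regime.

    Piecewise-ish image, smooth bias in [0.8, 1.2], small smooth
    difference field, random class means and a smooth random phi.
    """
    from scipy import ndimage

    h, w = shape
    means = rng.uniform(40.0, 220.0, n_classes)
    labels = (rng.random((h, w)) * n_classes).astype(int)
    labels = ndimage.grey_closing(labels, size=3)
    I = means[labels] + rng.normal(0, 5.0, (h, w))
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    if smooth_fields:
        sy, sx = rng.uniform(-0.2, 0.2, 2)
        b = 1.0 + sy * (rows / max(h - 1, 1) - 0.5) + sx * (cols / max(w - 1, 1) - 0.5)
        d = ndimage.gaussian_filter(rng.normal(0, 1.0, (h, w)), 3.0) * 3.0
    else:
        b = rng.uniform(0.5, 1.5, (h, w))
        d = rng.normal(0.0, 10.0, (h, w))
    c = rng.uniform(20.0, 240.0, n_classes)
    phi = ndimage.gaussian_filter(rng.normal(0, 1.0, (h, w)), 2.0)
    phi *= 5.0 / max(np.abs(phi).max(), 1e-9)
    return I, b, d, c, phi
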