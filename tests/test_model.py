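"""Closed-form updates, fit maps and the energy functional."""

import numpy as np
import pytest

from lrdseg.exceptions import DegenerateBiasError, DegenerateClassError
from lrdseg.model import (
    BiasModel,
    ModelParams,
    corrected_image,
    fit_maps,
    memberships_2p,
    normalize_bias,
    total_energy,
    update_b,
    update_c,
    update_d,
)
from lrdseg.numerics import build_kernel, local_convolve
from lrdseg.phantoms import generate, get_spec

import oracles
from conftest import random_instance


def crisp_partition(rng, shape, n_classes=2):
    labels = (rng.random(shape) * n_classes).astype(int)
    return [(labels == i).astype(float) for i in range(n_classes)]


@pytest.fixture()
def kernel():
    return build_kernel(1.5)  # 5x5 window keeps the loop oracles fast


class TestUpdateC:
    def test_constant_image_gives_constant_means(self, kernel):
        rng = np.random.default_rng(0)
        u = crisp_partition(rng, (10, 10))
        bias = BiasModel.initial((10, 10), 2)
        c = update_c(np.full((10, 10), 42.0), bias, u, kernel)
        np.testing.assert_allclose(c, 42.0, rtol=1e-12)

    def test_scaling_image_and_difference_scales_means(self, kernel):
        rng = np.random.default_rng(1)
        I, b, d, _, _ = random_instance(rng, (10, 10))
        u = crisp_partition(rng, (10, 10))
        bias = BiasModel(b=b, d=d, c=np.zeros(2))
        c1 = update_c(I, bias, u, kernel)
        c2 = update_c(3.0 * I, bias.with_(d=3.0 * d), u, kernel)
        np.testing.assert_allclose(c2, 3.0 * c1, rtol=1e-10)

    def test_matches_bruteforce_integrals(self, kernel):
        rng = np.random.default_rng(2)
        I, b, d, _, _ = random_instance(rng, (8, 8))
        u = crisp_partition(rng, (8, 8))
        bias = BiasModel(b=b, d=d, c=np.zeros(2))
        expected = oracles.brute_update_c(I, b, d, u, kernel.weights)
        np.testing.assert_allclose(update_c(I, bias, u, kernel), expected, rtol=1e-10)

    def test_degenerate_class_raises_with_index(self, kernel):
        u = [np.ones((8, 8)), np.zeros((8, 8))]
        bias = BiasModel.initial((8, 8), 2)
        with pytest.raises(DegenerateClassError) as exc:
            update_c(np.ones((8, 8)), bias, u, kernel)
        assert exc.value.class_index == 1

    def test_degenerate_class_frozen_with_prev(self, kernel):
        u = [np.ones((8, 8)), np.zeros((8, 8))]
        bias = BiasModel.initial((8, 8), 2)
        c = update_c(np.full((8, 8), 9.0), bias, u, kernel, prev=np.array([1.0, 77.0]))
        assert c[1] == 77.0
        np.testing.assert_allclose(c[0], 9.0, rtol=1e-12)


class TestUpdateB:
    def test_single_class_constant_image(self, kernel):
        v, beta0 = 50.0, 1.3
        u = [np.ones((10, 10))]
        bias = BiasModel(b=np.ones((10, 10)), d=np.zeros((10, 10)), c=np.array([v]))
        b = update_b(np.full((10, 10), beta0 * v), bias, u, kernel)
        np.testing.assert_allclose(b, beta0, rtol=1e-12)

    def test_recovers_slowly_varying_ramp(self):
        kernel = build_kernel(3.0)
        rows, cols = np.mgrid[0:40, 0:40].astype(float)
        b_true = 0.8 + 0.4 * (rows + cols) / 78.0  # linear, in [0.8, 1.2]
        c1 = 100.0
        u = [np.ones((40, 40))]
        bias = BiasModel(b=np.ones((40, 40)), d=np.zeros((40, 40)), c=np.array([c1]))
        b = update_b(b_true * c1, bias, u, kernel)
        interior = (slice(7, -7), slice(7, -7))
        assert np.abs(b[interior] / b_true[interior] - 1.0).max() < 0.02

    def test_matches_bruteforce(self, kernel):
        rng = np.random.default_rng(3)
        I, b, d, c, _ = random_instance(rng, (8, 8))
        u = crisp_partition(rng, (8, 8))
        bias = BiasModel(b=b, d=d, c=c)
        expected = oracles.brute_update_b(I, b, d, c, u, kernel.weights)
        np.testing.assert_allclose(update_b(I, bias, u, kernel), expected, rtol=1e-10)

    def test_zero_means_degenerate(self, kernel):
        u = crisp_partition(np.random.default_rng(4), (8, 8))
        bias = BiasModel(b=np.ones((8, 8)), d=np.zeros((8, 8)), c=np.zeros(2))
        with pytest.raises(DegenerateBiasError):
            update_b(np.ones((8, 8)), bias, u, kernel)


class TestUpdateD:
    def test_exact_fit_gives_zero(self, kernel):
        rng = np.random.default_rng(5)
        _, b, _, c, _ = random_instance(rng, (10, 10))
        u = crisp_partition(rng, (10, 10))
        J = c[0] * u[0] + c[1] * u[1]
        bias = BiasModel(b=b, d=np.zeros((10, 10)), c=c)
        d = update_d(b * J, bias, u, kernel)
        np.testing.assert_allclose(d, 0.0, atol=1e-10)

    def test_zero_bias_gives_smoothed_image(self, kernel):
        rng = np.random.default_rng(6)
        I = rng.random((9, 9)) * 200
        u = crisp_partition(rng, (9, 9))
        bias = BiasModel(b=np.zeros((9, 9)), d=np.zeros((9, 9)), c=np.array([3.0, 7.0]))
        d = update_d(I, bias, u, kernel)
        np.testing.assert_allclose(
            d, local_convolve(I, kernel) / local_convolve(np.ones_like(I), kernel),
            rtol=1e-12,
        )

    def test_matches_bruteforce(self, kernel):
        rng = np.random.default_rng(7)
        I, b, d, c, _ = random_instance(rng, (8, 8))
        u = crisp_partition(rng, (8, 8))
        bias = BiasModel(b=b, d=d, c=c)
        expected = oracles.brute_update_d(I, b, c, u, kernel.weights)
        np.testing.assert_allclose(update_d(I, bias, u, kernel), expected, rtol=1e-10)


class TestFitMaps:
    def test_perfect_constant_fit_is_zero(self, kernel):
        b = np.full((9, 9), 1.1)
        d = np.full((9, 9), 4.0)
        c = np.array([80.0])
        bias = BiasModel(b=b, d=d, c=c)
        f = fit_maps(b * c[0] + d, bias, kernel)
        np.testing.assert_allclose(f[0], 0.0, atol=1e-9)

    def test_nonnegative(self, kernel):
        rng = np.random.default_rng(8)
        I, b, d, c, _ = random_instance(rng, (10, 10), smooth_fields=False)
        f = fit_maps(I, BiasModel(b=b, d=d, c=c), kernel)
        for fi in f:
            assert fi.min() > -1e-8 * max(1.0, np.abs(fi).max())

    def test_expansion_matches_literal_double_loop(self, kernel):
        rng = np.random.default_rng(9)
        I, b, d, c, _ = random_instance(rng, (6, 6))
        f = fit_maps(I, BiasModel(b=b, d=d, c=c), kernel)
        for ci, fi in zip(c, f):
            expected = oracles.brute_fit_map(I, b, d, ci, kernel.weights)
            np.testing.assert_allclose(fi, expected, rtol=1e-9, atol=1e-9)


class TestTotalEnergy:
    def test_perfect_fit_leaves_length_term(self):
        # straight vertical contour, signed-distance phi, alpha = 0
        params = ModelParams(sigma=1.5, alpha=0.0, beta=10.0)
        kernel = build_kernel(params.sigma)
        shape = (20, 20)
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        phi = cols - 9.5
        spec = params.step_spec
        h = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / spec.epsilon))
        # constant classes fit the image exactly -> data term vanishes
        bias = BiasModel(b=np.ones(shape), d=np.zeros(shape), c=np.array([7.0, 7.0]))
        I = np.full(shape, 7.0)
        # independent length measure through the smoothed Heaviside
        hp = np.pad(h, 1, mode="edge")
        hy = 0.5 * (hp[2:, 1:-1] - hp[:-2, 1:-1])
        hx = 0.5 * (hp[1:-1, 2:] - hp[1:-1, :-2])
        expected = params.beta * np.sum(np.hypot(hx, hy))
        assert total_energy(I, bias, [phi], params, kernel) == pytest.approx(
            expected, rel=1e-10
        )

    def test_nonnegative_for_nonnegative_weights(self):
        rng = np.random.default_rng(10)
        params = ModelParams(sigma=1.5)
        kernel = build_kernel(params.sigma)
        for _ in range(5):
            I, b, d, c, phi = random_instance(rng, (10, 10))
            e = total_energy(I, BiasModel(b=b, d=d, c=c), [phi], params, kernel)
            assert e >= 0.0

    def test_data_term_matches_quadruple_loop(self):
        rng = np.random.default_rng(11)
        params = ModelParams(sigma=1.5, alpha=0.0, beta=0.0)
        kernel = build_kernel(params.sigma)
        I, b, d, c, phi = random_instance(rng, (8, 8))
        u = memberships_2p(phi, params.step_spec)
        expected = oracles.brute_data_energy(I, b, d, c, u, kernel.weights)
        got = total_energy(I, BiasModel(b=b, d=d, c=c), [phi], params, kernel)
        assert got == pytest.approx(expected, rel=1e-8)


class TestMinimizerProperty:
    """Each closed-form update must not increase the energy.

    Instances follow the model's slow-variation regime (smooth bias and
    difference fields), where the printed updates are minimizers.
    """

    @pytest.mark.parametrize("seed", range(10))
    def test_updates_never_increase_energy(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = ModelParams(sigma=1.5, alpha=0.0, beta=0.0)
        kernel = build_kernel(params.sigma)
        I, b, d, c, phi = random_instance(rng, (16, 16))
        bias = BiasModel(b=b, d=d, c=c)
        u = memberships_2p(phi, params.step_spec)

        def energy(bm):
            return total_energy(I, bm, [phi], params, kernel)

        e0 = energy(bias)
        # each update applied with the other unknowns held at the
        # instance state
        after_c = bias.with_(c=update_c(I, bias, u, kernel))
        after_b = bias.with_(b=update_b(I, bias, u, kernel))
        after_d = bias.with_(d=update_d(I, bias, u, kernel))
        for updated in (after_c, after_b, after_d):
            assert energy(updated) <= e0 * (1 + 1e-9) + 1e-9


class TestBaselineReduction:
    """With d = 0 the updates are algebraically Li's model."""

    def test_updates_bitwise_equal_to_independent_li(self):
        rng = np.random.default_rng(12)
        params = ModelParams(sigma=3.0, baseline_li=True)
        kernel = build_kernel(params.sigma)
        g = oracles.li_kernel_1d(params.sigma)
        for _ in range(5):
            I, b, _, c, phi = random_instance(rng, (12, 12))
            u = memberships_2p(phi, params.step_spec)
            bias = BiasModel(b=b, d=np.zeros_like(b), c=c)
            np.testing.assert_array_equal(
                update_b(I, bias, u, kernel), oracles.li_update_b(I, c, u, g)
            )
            np.testing.assert_array_equal(
                update_c(I, bias, u, kernel), oracles.li_update_c(I, b, u, g)
            )


class TestDifferenceFieldRole:
    """d vanishes on well-fit data and tracks artifact amplitude."""

    def test_artifact_amplitude_drives_local_difference(self):
        ph = generate(get_spec("tshape-clean"))
        kernel = build_kernel(3.0)
        params = ModelParams()
        u = [(ph.true_labels == 2).astype(float), (ph.true_labels == 1).astype(float)]
        patch = (slice(90, 105), slice(90, 105))  # background area
        peaks = []
        for amp in (10.0, 20.0, 40.0):
            I = ph.image.copy()
            I[patch] += amp
            bias = BiasModel.initial(I.shape, 2)
            prev = None
            for _ in range(5):
                bias = bias.with_(c=update_c(I, bias, u, kernel, prev=prev))
                prev = bias.c
                bias = bias.with_(b=update_b(I, bias, u, kernel))
                bias = bias.with_(d=update_d(I, bias, u, kernel))
            peaks.append(np.abs(bias.d[patch]).max())
        assert peaks[0] < peaks[1] < peaks[2]
        assert peaks[0] > 1.0  # the artifact is actually picked up


class TestHelpers:
    def test_corrected_image_inverts_forward_model(self):
        rng = np.random.default_rng(13)
        I, b, d, c, _ = random_instance(rng, (10, 10))
        bias = BiasModel(b=b, d=d, c=c)
        np.testing.assert_allclose(corrected_image(I, bias) * b + d, I, rtol=1e-10)

    def test_normalize_bias_fixes_scale_and_preserves_product(self):
        rng = np.random.default_rng(14)
        _, b, d, c, _ = random_instance(rng, (10, 10))
        bias = BiasModel(b=2.0 * b, d=d, c=c)
        norm = normalize_bias(bias)
        assert np.mean(norm.b) == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(
            np.multiply.outer(norm.c, norm.b), np.multiply.outer(bias.c, bias.b),
            rtol=1e-10,
        )
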