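"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as literal transcriptions of the
model's defining formulas — clamped-index double loops and straight-line
array expressions — kept independent of the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def gaussian_window(sigma: float) -> np.ndarray:
    """Truncated normalized Gaussian window, (4k+1)^2, k = ceil(sigma)-1."""
    k = max(int(np.ceil(sigma)) - 1, 1)
    half = 2 * k
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    w = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    return w / w.sum()


def brute_convolve(field: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Windowed sum with clamped (replicate-edge) indexing."""
    h, w = field.shape
    m = weights.shape[0] // 2
    out = np.zeros_like(field, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in range(-m, m + 1):
                for dc in range(-m, m + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    acc += weights[m + dr, m + dc] * field[rr, cc]
            out[r, c] = acc
    return out


def brute_update_b(I, b, d, c, u, weights):
    J1 = sum(ci * ui for ci, ui in zip(c, u))
    J2 = sum(ci**2 * ui for ci, ui in zip(c, u))
    return brute_convolve((I - d) * J1, weights) / brute_convolve(J2, weights)


def brute_update_c(I, b, d, u, weights):
    kb = brute_convolve(b, weights)
    kb2 = brute_convolve(b**2, weights)
    return np.array(
        [
            np.sum(kb * (I - d) * ui) / np.sum(kb2 * ui)
            for ui in u
        ]
    )


def brute_update_d(I, b, c, u, weights):
    M1 = sum((I - b * ci) * ui for ci, ui in zip(c, u))
    M2 = sum(np.asarray(ui, dtype=float) for ui in u)
    return brute_convolve(M1, weights) / brute_convolve(M2, weights)


def brute_fit_map(I, b, d, ci, weights):
    """f_i(x) = sum_y K(y-x) (I(x) - b(y) c_i - d(y))^2 by literal loops."""
    h, w = I.shape
    m = weights.shape[0] // 2
    out = np.zeros_like(I, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in range(-m, m + 1):
                for dc in range(-m, m + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    acc += weights[m + dr, m + dc] * (
                        I[r, c] - b[rr, cc] * ci - d[rr, cc]
                    ) ** 2
            out[r, c] = acc
    return out


def brute_data_energy(I, b, d, c, u, weights):
    """Quadruple-loop data term: sum_i sum_x u_i(x) f_i(x)."""
    total = 0.0
    for ci, ui in zip(c, u):
        total += float(np.sum(ui * brute_fit_map(I, b, d, ci, weights)))
    return total


def brute_laplacian(phi):
    h, w = phi.shape
    out = np.zeros_like(phi, dtype=float)
    for r in range(h):
        for c in range(w):
            up = phi[max(r - 1, 0), c]
            dn = phi[min(r + 1, h - 1), c]
            lf = phi[r, max(c - 1, 0)]
            rt = phi[r, min(c + 1, w - 1)]
            out[r, c] = up + dn + lf + rt - 4.0 * phi[r, c]
    return out


# --- independent transcription of the baseline (d-free) model -------------

def _sep_conv(field, g):
    out = ndimage.convolve1d(np.asarray(field, float), g, axis=0, mode="nearest")
    return ndimage.convolve1d(out, g, axis=1, mode="nearest")


def li_kernel_1d(sigma: float) -> np.ndarray:
    k = max(int(np.ceil(sigma)) - 1, 1)
    off = np.arange(-2 * k, 2 * k + 1, dtype=float)
    g = np.exp(-(off**2) / (2.0 * sigma**2))
    return g / g.sum()


def li_update_b(I, c, u, g):
    J1 = sum(ci * ui for ci, ui in zip(c, u))
    J2 = sum(ci**2 * ui for ci, ui in zip(c, u))
    return _sep_conv(I * J1, g) / _sep_conv(J2, g)


def li_update_c(I, b, u, g):
    kb = _sep_conv(b, g)
    kb2 = _sep_conv(b**2, g)
    return np.array([np.sum(kb * I * ui) / np.sum(kb2 * ui) for ui in u])


def li_two_phase_trajectory(I, init_mask, params, n_iters):
    """Straight-line transcription of the baseline two-phase evolution.

    Mirrors the driver's loop structure (memberships, c/b updates, fit
    maps, inner explicit steps) with every array expression written out
    independently; returns the list of phi arrays after each outer
    iteration plus the final (b, c).
    """
    eps = params.epsilon
    g = li_kernel_1d(params.sigma)
    c0 = params.resolved_c0(1)
    phi = np.where(np.asarray(init_mask, bool), c0, -c0).astype(float)

    def H(s):
        return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(s / eps))

    def delta(s):
        return (eps / np.pi) / (eps**2 + s**2)

    def grad(f):
        fp = np.pad(f, 1, mode="edge")
        return (
            0.5 * (fp[2:, 1:-1] - fp[:-2, 1:-1]),
            0.5 * (fp[1:-1, 2:] - fp[1:-1, :-2]),
        )

    def curv(f):
        gy, gx = grad(f)
        mag = np.sqrt(gx**2 + gy**2 + 1e-10)
        dyy, _ = grad(gy / mag)
        _, dxx = grad(gx / mag)
        return dyy + dxx

    def lap(f):
        fp = np.pad(f, 1, mode="edge")
        return fp[2:, 1:-1] + fp[:-2, 1:-1] + fp[1:-1, 2:] + fp[1:-1, :-2] - 4.0 * f

    h = H(phi)
    u = [h, 1.0 - h]
    kb = _sep_conv(np.ones_like(I), g)
    kb2 = kb
    c = np.array([np.sum(kb * I * ui) / np.sum(kb2 * ui) for ui in u])
    b = np.ones_like(I)

    phis = []
    for _ in range(n_iters):
        h = H(phi)
        u = [h, 1.0 - h]
        c = li_update_c(I, b, u, g)
        b = li_update_b(I, c, u, g)
        k_one = _sep_conv(np.ones_like(I), g)
        f = []
        for ci in c:
            a = b * ci
            f.append(I**2 * k_one - 2.0 * I * _sep_conv(a, g) + _sep_conv(a**2, g))
        for _ in range(params.inner_steps):
            dlt = delta(phi)
            kappa = curv(phi)
            phi = phi + params.dt * (
                dlt * (f[1] - f[0])
                + params.alpha * (lap(phi) - kappa)
                + params.beta * dlt * kappa
            )
        phis.append(phi.copy())
    return phis, b, c
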