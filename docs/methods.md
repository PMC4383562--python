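# Methods

## Model

The measured image is modeled as `I = b·J + d + n` on a 0–255 working
scale: `J` is piecewise constant with class means `c_i` on a partition
`{Ω_i}` (assumption: the true tissue intensities are approximately
constant within each class), `b` is a multiplicative bias field assumed
to vary slowly relative to the kernel scale, `d` is an additive local
difference field capturing what the `b·J` approximation misses
(highlights, fuzzy boundaries, locally similar classes), and `n` is
additive Gaussian noise.

Segmentation minimizes the local clustering energy

    E(b, c, d, φ) = Σ_i Σ_x u_i(φ(x)) f_i(x) + α P(φ) + β L(φ)
    f_i(x) = Σ_y K_σ(y − x) (I(x) − b(y) c_i − d(y))²

where `K_σ` is a truncated Gaussian window of size `(4k+1)×(4k+1)` with
`k` the greatest integer strictly below `σ`, renormalized to unit sum so
that convolving a constant returns the constant; `u_i` are
smoothed-Heaviside memberships of the level-set partition
(`H_ε(s) = ½(1 + (2/π) arctan(s/ε))`); `P(φ) = ½Σ(|∇φ|−1)²` penalizes
deviation from a signed distance function (replacing periodic
re-initialization); and `L(φ) = Σ|∇H_ε(φ)|` measures contour length.
For three classes, two level sets define
`u1 = H(φ1)H(φ2)`, `u2 = H(φ1)(1−H(φ2))`, `u3 = 1−H(φ1)`,
which always sum to one.

Minimization alternates:

1. closed-form updates, in the order c → b → d, each using the most
   recently updated quantities:
   `c_i = ∫(K*b)(I−d)u_i / ∫(K*b²)u_i`,
   `b = K*((I−d)·J⁽¹⁾) / K*(J⁽²⁾)` with `J⁽ⁿ⁾ = Σ c_iⁿ u_i`,
   `d = K*(Σ(I−b c_i)u_i) / K*(Σu_i)`;
2. explicit Euler steps of the gradient flow
   `∂φ/∂t = δ_ε(φ)(f2−f1) + α(∇²φ − div(∇φ/|∇φ|)) + β δ_ε(φ) div(∇φ/|∇φ|)`
   (two-phase; the three-phase flows carry the extra membership factors
   and are the exact negative functional derivatives of the data term,
   which the test suite verifies by finite differences). φ1 is stepped
   before φ2; the fit maps are frozen within an outer iteration.

The closed-form updates are exact coordinate minimizers in the limit
where `b` and `d` are locally constant under the kernel (the model's
slow-variation regime); elsewhere they are descent steps with a small
systematic bias, discussed under *Limitations*.

With `baseline_li=True` the difference field is clamped to zero and the
updates reduce algebraically to the local-intensity-clustering baseline
model; the test suite checks bit-level agreement with an independently
coded transcription of that baseline.

## Membership handling and the final refit

During evolution the closed-form updates consume the smoothed
memberships `u_i(φ)`, exactly as in the gradient-flow derivation. This
softness is functionally important: it couples the classes everywhere,
which keeps the contour mobile and the method insensitive to where the
initial seeds are placed (with crisp in-loop memberships the free-form
bias field absorbs the misfit region by region and the contour freezes —
we verified this empirically). The price is that the arctan Heaviside
has slowly decaying tails (`1 − H(s) ≈ ε/(πs)`), so even a converged φ
leaks ~1% of every class into every estimate, which measurably distorts
the joint `(b, c)` fixed point.

The reported `(b, c, d)` are therefore re-estimated after convergence on
the crisp final partition (`refit_on_partition`): 30 passes of the same
closed forms, from the neutral state `b ≡ 1, d ≡ 0`, with indicator
memberships. This is estimation on the model's actual partition `Ω_i` —
the closed forms are derived over crisp partitions, with `H_ε`
introduced only to make the level-set evolution differentiable. The
bias field is reported mean-normalized (`mean(b) = 1`, `c` rescaled
accordingly) because `(b, c)` are only identified up to a reciprocal
scale; the corrected image is `(I − d)/b` with `b` floored at 1e-6.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `sigma` | 3 px | kernel std; window `(4k+1)²`, `k = ⌈σ⌉−1` |
| `epsilon` | 1 | Heaviside/Dirac smoothing width |
| `dt` | 0.1 | explicit time step |
| `alpha` | 0.1/dt | distance-regularization weight |
| `beta` | 0.003·255² | length weight (presumes the 0–255 scale) |
| `max_iters` | 200 (2-phase), 400 (3-phase) | outer iteration cap |
| `inner_steps` | 5 | explicit PDE substeps per outer update cycle |
| `conv_tol` | 1e-5 | label-change fraction threshold, checked every 5 outer iterations |
| `c0` | 2 (2-phase), 10 (3-phase) | binary initialization magnitude |
| `refit_passes` | 30 | closed-form passes of the final crisp refit |

Two defaults deserve comment. *Inner substeps*: each closed-form pass is
cheap but one explicit, CFL-limited PDE step per pass makes the contour
crawl; five substeps per cycle let a 128×128 image converge reliably
within 200 outer iterations across noise realizations, without touching
the time step. *c0*: the two-phase driver keeps the conventional small
binary magnitude (a soft start leaves the far field responsive through
the Dirac tails), whereas the three-phase membership products compound
the arctan tails quadratically — with `c0 = 2` a small class's mean is
blended away at initialization — so the three-phase driver starts at
`±10`.

The convergence rule is the fraction of pixels whose label changed
between checks (every 5 outer iterations) falling below `conv_tol`;
1e-5 on a 128² grid means essentially no pixel moved, which avoids
stopping during slow transients while still triggering (typically
~125–165 outer iterations for two-phase, ~210–300 for three-phase on
the default phantoms).

## Synthetic phantoms

The generator emulates the forward model directly: a piecewise-constant
class image (T-shape, star with satellite disks, disks, or three nested
wavy regions standing in for WM/GM/CSF geometry), multiplied by a smooth
bias field (linear ramp, Gaussian bump, or low-order polynomial; mean
normalized to 1, max/min ratio set by `bias_range`), plus i.i.d.
Gaussian noise, clipped to [0, 255] with the clipped fraction reported
(default specs never clip). Bias smoothness respects the slow-variation
assumption (<10% relative change over any kernel-radius neighborhood).

What the phantoms deliberately do not model: anatomical texture and
partial-volume voxels, spatially correlated or Rician noise, and
scanner-specific coil profiles. Passing the recovery tests shows the
estimator is consistent under its own model assumptions — the intended
claim — not that it matches expert segmentations of clinical data.

## Evaluation

Overlap metrics follow the convention: Jaccard `JS = |O|/|S_g ∪ S_m|`,
Dice `DSC = 2|O|/(|S_g|+|S_m|)`, and the paired ratios
`RFP = |S_g \ O|/|S_g|`, `RFN = |S_m \ O|/|S_m|` — note these
denominators differ from conventional false-positive/negative rates;
under them RFP measures ground truth left uncovered and RFN the model
mask outside the truth. Empty masks raise rather than silently return
0/0. Three-phase label maps are scored after best-match label
permutation, since class indices are assigned by seed placement.

## Numerical choices

- Derivatives: central differences on a unit grid; 5-point Laplacian;
  replicate-edge padding everywhere (the discrete Neumann condition).
- Curvature uses the stabilized magnitude `sqrt(φ_x² + φ_y² + 1e-10)`.
- Convolution is separable (the normalized square-window Gaussian is an
  outer product); it matches a literal clamped window sum to float
  round-off.
- Degenerate guards: convolution denominators floored at 1e-12 (error on
  violation); a class whose membership mass falls below 1e-6 of the
  image area keeps its previous mean rather than aborting a run, except
  on the first iteration where it is an error.
- Non-finite φ after a step raises a divergence error naming the
  iteration and suggesting a smaller `dt`.

## Limitations

- The `b`/`d` split is only weakly identified where the bias field has
  curvature at the kernel scale: the energy's own optimum moves part of
  such a field into `d` (we verified that exact coordinate descent
  reaches lower energy with a *less* faithful `b` than the printed
  updates). Bias-recovery correlations are accordingly ≈0.995 for
  ramp-like fields but plateau near ≈0.97 for a Gaussian bump; the
  segmentation itself is unaffected.
- Near the contour the data force (scale `(c_i − c_j)²`) dwarfs `α`, so
  φ develops a steep collar there; the distance regularizer maintains
  `|∇φ| ≈ 1` only outside that collar. This is cosmetic for
  segmentation but means φ is not a usable distance map within a few
  pixels of the boundary.
- Three-phase class arrangement depends on seed placement (the
  membership construction is asymmetric in φ1/φ2); seeds should roughly
  cover the structures of interest. Complementing the second seed
  provably swaps classes 1 and 2 of the same partition.
- The explicit scheme can raise the energy slightly on individual
  iterations; descent holds in trend (≥95% of iterations on the default
  phantoms).
- 2-D only; N ∈ {2, 3} classes.
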