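# Methods

`srfield` implements two cortical-inspired mean-field models of primary
visual cortex (V1) activity as an image-processing pipeline, and uses them to
reproduce Poggendorff-type geometrical optical illusions on synthetic
stimuli.  This note records the model, its discretisation, the numerical and
design choices that were genuinely open, and what the tests do and do not
establish.

## Model

### Position–orientation space and lifting

V1 simple cells are indexed by retinal position and preferred orientation:
the model state lives on `M = R² × P¹`, with orientations on `[0, π)`
(antipodal directions identified).  A grey-scale image `f : Q → [0,1]` is
lifted to an activation `a₀(x, y, θ)` by filtering with *all-scale cake
wavelets*: angular slices of the 2D Fourier plane with normalised B-spline
angular profiles of order `bw` (default 5) centred at
`θ_k = kΔθ, Δθ = π/K, k = 1..K`, each slice merged with its antipode, radial
profile identically 1.  The B-spline refinement property makes the `K` slices
an exact partition of unity at every frequency, so the plain sum over
orientations inverts the lifting (`project(lift(f)) = f` to round-off); the
zero-frequency component is split uniformly (`1/K` per slice) so constant
images lift to orientation-uniform activations.

Two deliberate conventions:

* Activations are **real** — the lift keeps the real part of the complex
  filter response.  The evolutions apply real sigmoids, and nothing
  downstream uses phase.  The slices are additionally symmetrised under
  frequency negation (a no-op except on the Nyquist lines of even-sized
  grids), which makes every per-slice response exactly Hermitian and the
  discarded imaginary part pure round-off.
* The discrete reconstruction is a plain sum over `k` with no `Δθ` factor:
  the bank normalisation absorbs the angular measure, which is precisely
  what makes the round trip exact.

### Sub-Riemannian interaction kernel

Lateral connectivity in V1 propagates activity along oriented contours.
This is modelled by the hypoelliptic diffusion generated by the
sub-Laplacian

    L = X₁² + β² X₂²,   X₁ = cosθ ∂x + sinθ ∂y,   X₂ = ∂θ,

whose 3×3 diffusion tensor has eigenvalues `{0, β², 1}` for every `θ` — the
rank deficiency is the sub-Riemannian degeneracy.  `β > 0` couples spatial
and angular units; the default `β = K/(2√2·N)` encodes one spatial unit = two
pixel edges, one orientation unit = one pixel edge, and is always
configurable.

The semigroup `exp(τL)` is the neuronal interaction kernel: its inner time
`τ` sets the kernel width.  An isotropic 3D Gaussian (spatial std `σ_ω` px,
angular std `σ_ω·K/N` slices by default, both configurable) is provided as
the baseline kernel of the earlier cortical models it replaces.

### Heat solver

The spatial domain is the unit square with `N` samples per axis
(`Δx = 1/N`) and periodic boundaries.  Spatial central differences become,
after a 2D DFT, multiplication by `iN·d[r,s,k]` with
`d = cosθ_k·sin(2πs/N) + sinθ_k·sin(2πr/N)` (`s` indexes the x/column axis,
`r` the y/row axis — the array convention is `[row, column, slice]`).  The
heat equation then decouples into `N²` independent `K`-dimensional ODEs

    dΨ/dt = [Θ − N² diag(d²)] Ψ,

with `Θ = (β²/Δθ²)·circulant(1, −2, 1)` the periodic angular
second-difference operator.  Each ODE is integrated by Crank–Nicolson with
step `Δτ` (`m = round(τ/Δτ)` steps); the cyclic tridiagonal systems are
solved in `O(K)` by a Sherman–Morrison variant of the Thomas algorithm.  The
per-mode generator is symmetric negative semidefinite, so each CN step has
amplification magnitude ≤ 1 for every mode (unconditional L² stability), the
orientation-summed mass is conserved exactly (the zero mode is stationary),
and the scheme is second-order in `Δτ` (verified: error vs. the dense matrix
exponential drops by 4.0× when `Δτ` is halved).

Because the step matrix is constant, the `m`-step propagator is precomputed
per frequency from the eigendecomposition of the per-mode generator when the
flow is applied repeatedly (inside the model iterations); this path agrees
with explicit CN stepping to 1e−12 and makes each application one FFT pair
plus a batched `K×K` product.

A dense `(N²K)×(N²K)` generator + `expm` oracle, feasible up to
`N²K ≈ 4096`, is the independent reference in the tests and is never used in
the pipeline itself.

### Mean-field dynamics

With `a₀` the initial lift, `μ` its per-slice 2D Gaussian local mean
(std `σ_μ` px, periodic, evaluated spectrally so constants and per-slice
sums are preserved exactly), `λ ≥ 0` the fidelity weight and `M > 0` the
interaction normaliser:

* **WC (Wilson–Cowan):**
  `∂t a = −(1+λ)a + (1/2M)·exp(τL)σ(a) + λa₀ + μ`, with the decreasing
  saturating sigmoid `σ(r) = −min{1, max(α(r−1/2), −1)}` applied to local
  activity.  (A `negate_sigma` flag selects the increasing convention of the
  earlier literature.)
* **LHE (Local Histogram Equalisation):** the nonlinearity acts on local
  contrast, `σ̂(a(ξ) − a(η))` with `σ̂(r) = −σ(r+1/2) = clip(αr, −1, 1)`,
  integrated against the kernel.  The pairwise integral is made computable
  by a degree-`n` polynomial fit of `σ̂` (default `n = 7`, odd to match the
  sigmoid's symmetry): expanding the contrast binomially converts it into
  `n+1` kernel applications to elementwise powers of `a`, recombined with
  position-dependent coefficient fields.  The expansion identity is tested
  against a direct double-sum oracle to 1e−12.

Both flows are discretised by explicit gradient-descent steps of size `Δt`;
`Δt ≤ 1/(1+λ)` is the sufficient stability condition, and the configuration
warns beyond it.

**Polynomial fitting domain.**  The fit must cover the contrasts actually
visited.  Under the stability condition the iterates obey the a-priori bound
`‖a‖∞ ≤ max(‖a₀‖∞, (λ‖a₀‖∞ + ‖μ‖∞ + 1.2/(2M))/(1+λ))`, so the fit half-range
is 2.4× that bound (contrast range + 20 % margin), computed once from the
initial lift.  This is equivalent, up to an affine change of variable, to
rescaling contrasts into `[−1, 1]` and fitting on the unit interval.  For
strongly saturating sigmoids (`αR ≫ 1`) a degree-7 fit has sup error of
order 10⁻¹ near the plateaus; this is intrinsic to the polynomial device
(larger `n` helps, at `n+1` kernel applications per step) and does not
affect the linear contrast regime where the completion phenomena live.

**Energy.**  The implemented LHE step is exactly explicit gradient descent
on

    E(a) = λ/2 Σ|a−a₀|² + 1/2 Σ|a−μ|² − 1/(4M) ΣΣ k_τ(ξ,η) Σ̂(a(ξ)−a(η)),

where `Σ̂` is the even primitive of `σ̂` (`αr²/2` in the linear zone,
`|r| − 1/(2α)` beyond).  Symmetrising the double sum over the symmetric
kernel turns the `−1/(4M)` into the `+1/(2M)` interaction of the flow; the
quadratic fidelity terms dominate the linearly growing pairwise term, so `E`
is bounded below.  `lhe_energy` evaluates this with the dense kernel on
small grids; `lhe_energy_estimate` replaces `Σ̂` by the primitive of the
fitted polynomial and reuses the binomial expansion, giving a kernel-free
estimate at any grid size.  Monotone descent is verified per step with the
dense kernel.

**Fixed points.**  Constant images are *exact* LHE fixed points (the fitted
odd polynomial has `|c₀| ≲ 1e−16`, so zero contrast produces zero
interaction and the linear terms cancel); this is asserted to 1e−10 per
step.  They are not WC fixed points — `σ(c/K) ≠ 0` drives a uniform shift —
but slice-wise constancy is preserved by every operator, so a constant input
still yields a spatially constant output.

**A boundary-of-stability caveat.**  At exactly `Δt = 1/(1+λ)` the linear
damping of the explicit step vanishes and, for steep sigmoids (e.g.
`α = 20`), the WC iteration can close an exact period-2 cycle instead of
converging (observed numerically; the interaction Jacobian then has an
eigenvalue at −1).  The stability bound is therefore treated as a strict
interior condition: convergence is exercised at `Δt` strictly inside it,
where both models reach residual 1e−8 within tens of iterations on random
inputs.

### Discretisation variants

The update implemented is the discretisation of the continuous models above:
`a ← a + Δt[−(1+λ)a + S/(2M) + λa₀ + μ]`.  A published variant of the same
scheme weights the feedback as `a₀ + λμ` without the `1/(2M)`; it is
available behind the `discrete_as_printed` configuration flag but is not the
default, because the continuous models are what it discretises.

## Stimuli

The generator produces the two Poggendorff test figures on the integer pixel
grid with anti-aliasing off, so the grey-value set is exactly
`{background, bar, line}` (defaults 1.0 / 0.5 / 0.0 — maximal contrast;
published figures do not state grey levels) and geometry is assertable
exactly:

* **classical** — 200×200, vertical centred bar of width 30 px, one oblique
  transversal at incidence angle π/3 to the bar on the left, and on the
right both the collinear continuation and a segment vertically offset by
  `w/(2 tanφ)` (the offset is not stated in published figures and is a free
  parameter).  Occluded line portions are absent.
* **grating** — one global family of parallel stripes (default normal
  spacing 24 px, chosen to visually match the published figure; also a free
  parameter) interrupted by the same bar, so true continuations are
  collinear by construction.

Lines are stroked by perpendicular distance ≤ thickness/2 to the ideal line
(default thickness 2 px).  Pipeline boundary conditions are periodic, so
stimuli keep content away from borders.

## Experiment presets and problem sizes

All presets use N = 200, K = 16, bw = 5, M = 1.  Figure-matched parameter
sets: WC grating run (λ = 0.01, α = 20, σ_μ = 6.5, Δt = 0.1, Δτ = 0.01,
τ = 5); LHE grating run (α = 8, τ = 5, λ = 2, σ_μ = 1, Δt = 0.15,
Δτ = 0.01); LHE inner-time sweep (τ ∈ {0.1, 0.5, 1, 2.5, 5}, α = 6,
σ_μ = 1, Δt = 0.15, Δτ = 0.01 — no fidelity weight is published for this
sweep, so it reuses λ = 2 from the LHE grating run on the same stimulus);
LHE classical run (α = 8, τ = 2.5, λ = 0.5, σ_μ = 2.5, Δt = 0.15, Δτ = 0.1);
Gaussian-baseline runs with σ_ω = 12 (and λ = 0.7, α = 5, σ_μ = 2 for the
classical baseline, whose Δt is not published; 0.15 is used).  No outer
iteration count or tolerance is published; the defaults are a relative
residual of 1e−6 or 500 iterations, recorded in every snapshot.

Stopping residual is `‖A_p − A_{p−1}‖₂ / ‖A_{p−1}‖₂`; divergence (non-finite
residual, or growth over 100 consecutive iterations) aborts with a
diagnostic.  Output images are written raw (float TIFF, unclamped) and
display-normalised (8-bit PNG, min–max to [0,1]); normalisation never enters
the dynamics.

The test suite and the acceptance script run scaled-down problems chosen to
exercise every contract at interactive speed: dense-oracle comparisons on
8×8×4 (and 6×6×3 for the pairwise identity), dynamics contracts on 16×16×4,
and the perceptual properties on a 64×64, K = 8 grating with the preset
parameters' pixel-valued quantities scaled by 64/200 (σ_μ is floored at
0.5 px).  `τ` is *not* rescaled: the spatial domain is the unit square, so
the kernel width relative to the image is size-free.  Full-size 200×200,
K = 16 preset runs complete on one CPU in ~15 s (WC) to ~1 min (LHE, whose
steps need `n+1` kernel applications each) and are exercised through
`srfield preset` rather than the test suite.

## Perceptual metrics

Published illusion outputs are images judged by eye; the package therefore
asserts structural surrogates computed from its own outputs:

* **Propagation into the occluder:** after evolution, the dominant
  orientation slice (argmax over `k` of mean activation) inside the bar
  region equals the slice nearest the stripe orientation — not the vertical
  bar orientation — and the projected output inside the (input-constant)
  bar is non-constant.  Holds for both models at the grating parameters.
* **Inpainting vs. perceptual completion:** the darkest completion
  trajectory at bar mid-height is located and its horizontal distance to
  the nearest collinear stripe continuation measured.  At τ = 0.1 the
  offset is ~0.6 px (geometric completion); at τ = 5 it is ~1.4 px (biased,
  perceptual completion).  The monotone increase with τ is the tested
  property.

## Known limitations

* The partition-of-unity bank forces periodic boundary conditions; stimuli
  with content at the borders wrap around.
* The polynomial contrast device degrades in the deep-saturation regime
  (see above); the WC model at steep slopes can settle into period-2 cycles
  at the exact stability boundary.
* The synthetic stimuli are binary-valued line drawings with exact grey
  levels; natural images (texture, noise, graded contrast) are outside what
  the passing tests establish.  The perceptual metrics are surrogates for
  human psychophysics, not measurements of illusion strength.
* The analytic (Mathieu-function) expression of the sub-Riemannian heat
  kernel is deliberately not implemented; the spectral evolution replaces
  it.
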