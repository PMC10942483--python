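# Methods

`pinndiff` recovers a spatially varying diffusion coefficient D(x, y) from
spatio-temporal observations of a passive-scalar concentration c(x, y, t).
This note records the model, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## The inverse model

The data are an unordered point cloud {(xᵢ, yᵢ, tᵢ, cᵢ)} on the
dimensionless unit square and unit time interval (space scaled by a length
L, time by T, intensity by its global maximum; diffusivity then carries the
factor T/L²).  Two dense tanh networks are trained jointly:

- c̃(x, y, t; θ) — a surrogate for the concentration field;
- D̃(x, y; φ) — the diffusivity map, passed through a softplus so it stays
  positive (configurable to an unconstrained identity output).

They are coupled through the variable-coefficient diffusion operator

    f(c, D) = ∂x c ∂x D + ∂y c ∂y D + D (∂xx c + ∂yy c) = ∇·(D ∇c)

and the backward-Euler physics-informed concentration

    c_pi(t, x, y) = c̃(t + Δt, x, y) − Δt · f(c̃, D̃)|at (t + Δt),

with Δt the observation frame spacing (inferred as the median spacing of
the unique observation times unless given).  The objective is the sum of a
data misfit and a consistency penalty, both normalized by the standard
deviation σ_c of the observed concentrations:

    MSE = (1/N) Σ ((c̃ − c)/σ_c)² + (1/N_e) Σ ((c_pi − c̃)/σ_c)².

The two terms are weighted 1:1; σ_c-normalization is the only scaling.
Constant observations (σ_c = 0, up to rounding) are rejected: the
normalization is undefined and a gradient-free field carries no information
about D anyway.  Regions where ∇c vanishes contribute nothing to the
consistency term's dependence on D̃, so the recovered map is only loosely
constrained there — softplus positivity and the network's smoothness bias
fill in those regions, and errors there are *included* in the reported
global error metric.

All input derivatives of the networks are exact: forward-mode chain-rule
recurrences propagate first and pure second derivatives through the layers
(tanh is twice differentiable, which is why the activation is not
configurable), and a compact reverse-mode engine (`pinndiff.autodiff`)
supplies parameter gradients of the whole composite objective.  Finite
differences appear only in tests, as independent oracles.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with an exponential-staircase
learning rate lr·rate^(step // decay_steps); defaults lr = 1e−3, rate = 0.8
and 20 stairs over the run, i.e. a ~100× decay ending near 1e−5.  Each
iteration draws a minibatch without replacement from the cloud; the physics
consistency is enforced at the same spatial locations with times resampled
uniformly over [t_min, t_max − Δt].  Training runs in float32 by default —
the customary precision for this model class — with a float64 option; all
randomness derives from one seed, so runs are bitwise reproducible on a
platform.  A non-finite loss aborts with the iteration index after
restoring the last checkpointed parameters.

Initialization is Glorot-uniform with zero biases, except the D-network's
output bias, seeded so that softplus(bias) equals `d_init` (default 0.2, an
order-of-magnitude guess in the middle of the benchmark range).  Inputs are
affinely mapped to [−1, 1] inside the networks.

## The forward solver and synthetic benchmarks

The data generator integrates ∂c/∂t = ∇·(D∇c) with a conservative
finite-volume scheme on a cell-centered uniform grid: face diffusivities by
arithmetic mean (harmonic optional for near-discontinuous D), Peaceman–
Rachford ADI with Crank–Nicolson weighting, and a backward-Euler Rannacher
startup (4 substeps on the first frame interval) that damps the
high-frequency content rough initial data would otherwise ring on.
Zero-flux runs conserve mass to rounding error; Dirichlet cells use
linear ghost extrapolation, which preserves second-order accuracy (the
refinement guard asserts observed order ≈ 2 on a smooth closed-form
problem).

Four named diffusivity landscapes are built in: a paraboloid (case I), two
sinusoidal fields at increasing frequency (II, III), and a tanh-smoothed
four-quadrant step (IV) mimicking abrupt tissue heterogeneity.  The
benchmark concentration movie is driven by dye influx from the domain
edges: c = 0 initially, with the four edges held at graded concentrations
(left 1.0, top 0.75, right 0.5, bottom 0.25).  This mirrors
the reservoir-fed hydrogel experiments the method targets and sweeps
concentration gradients across the entire domain during t ∈ (0, 1), which
is what makes D identifiable everywhere.  An interior-blob initial
condition (smoothed disc, zero-flux walls) is also provided; at the reduced
grids used for testing its sharp spreading front is substantially harder to
regress, and identifiability away from the front is poor, so it is not the
default study condition (see `forward.disc_initial_condition`).

The synthetic "experimental movie" generator composes the same solver with
a piecewise-constant two-region diffusivity (stacked layers, or a disc
inclusion in a square), edge-source boundary conditions, additive Gaussian
intensity noise (default sd = 1% of the dynamic range; the robustness dial,
not an estimate of any particular camera), and 16-bit quantization.  Image
ingestion assumes intensity ∝ concentration and divides by the stack-wide
maximum — per-frame normalization would corrupt the temporal derivative the
physics residual relies on.  What these synthetic movies do *not* emulate:
flat-field/vignetting artifacts, registration drift, photobleaching, or
the 3-D optical distortion of a real cuvette; conclusions from passing
tests are about the inverse machinery, not about those confounders.

## Problem sizes and profiles

The full-scale configuration (500² mesh, 100 frames, two 8×128 networks,
5000-point batches, tens of thousands of Adam steps) is available as the
`full` CLI profile.  The test suite and the acceptance script run a
scaled-down profile chosen as this package's CPU-scale study condition:
128² mesh, the same 100 frames (the frame count sets the backward-Euler
Δt, which enters the residual's bias linearly, so it is kept at the
full-scale value; only the mesh and networks shrink), 4×48 networks,
512-point batches, 8000 observed spatial locations, and 10k–30k
iterations.  Error bounds asserted at that scale (normalized error of D̃
under 0.10 on the case-I benchmark; pointwise recovery of a constant D
within 5% over the interior) are the scaled stand-ins for the
full-scale figures; at the iteration budgets a single CPU affords, the
measured errors plateau roughly an order of magnitude above those bounds
(the limitation section below explains why), and the corresponding tests
report that honestly.

## Error metric

ℒ(a, a_pred) = ‖a − a_pred‖₂ / ‖a − ā‖₂ over the full evaluation grid, ā
the mean of the reference — exactly zero iff the fields agree, one for the
constant-mean predictor, and invariant to affine rescaling of both
arguments (so it is meaningful for diffusivities known only up to the
nondimensionalization).  It is undefined (and rejected) for a constant
reference; the two-region movie truths and the four benchmarks are all
non-constant.  Constant-D recovery is therefore reported as pointwise
relative deviation |D̃ − D|/D instead.

## Known limitations

- Identifiability is local: where the concentration never develops a
  gradient, D̃ reports the network prior, not the medium.
- The consistency term couples to D̃ through a factor Δt, so D̃ converges
  more slowly than c̃; short runs under-converge D̃ first, and near the
  end of training D̃ wanders within a band set by minibatch gradient noise
  rather than improving monotonically.
- Recovery quality is bounded by the concentration surrogate's *second*
  derivatives, which demand far more capacity and optimization than a
  point fit: a surrogate with R² ≈ 0.99 against the data can still carry
  tens of percent of error in its Laplacian, and D̃ inherits that error.
  This is the dominant error source at the CPU-scale profile.
- The backward-Euler residual has an O(Δt) one-sided bias: a least-squares
  fit of a constant D to exact 100-frame data already lands ~4% high early
  in the movie.  The pairing follows the one-sided definition by design; a
  time-centered stencil would cancel the leading term but is out of scope.
- No advection, reaction, anisotropy or uncertainty quantification.
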