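# Methods

`elastract` estimates planar fiber tracts between two fixed endpoints by
evolving a discrete curve under the gradient of a posterior energy.  This
note records the model, the numerical choices behind it, and what the
synthetic experiments do and do not establish.

## The posterior energy

A candidate fiber is a curve β : [0,1] → D = [0,1]², sampled at T points on
a uniform parameter grid.  The estimate minimizes

    E_total(β) = λ₁ E_data(β) + λ₂ E_prior(β) + λ₃ E_smooth(β)

with nonnegative weights (default (0.8, 0.1, 0.1), the setting used in the
simulated experiments).

**Data term (tensor fields).**  With M(x) a field of 2×2 SPD diffusion
tensors and n(t) the unit tangent,

    E_data = ∫₀¹ n(t)ᵀ M(β(t))⁻¹ n(t) dt.

The integrand depends only on the tangent *direction*, so the term measures
alignment with the dominant diffusion directions without penalizing length
(length is a separate term).  A speed-weighted variant (measure |β̇|dt),
which buys full reparameterization invariance, is available behind a flag
and off by default.

**Data term (ODF fields).**  With f_x an antipodally symmetric density on
the circle, E_data = ∫ −f_{β(t)}(n(t)) dt.  ODFs are stored as truncated
even-order Fourier series (default order 8), so circular derivatives are
analytic; spatial derivatives come from central differences of the
coefficients on the grid.

**Smoothness.**  E_smooth = ∫ |β̇| dt is the curve length; its gradient is
the curvature flow κn.  We orient the gradient *away* from the curvature
center — the first variation of length — so that a descent step is the
curve-shortening flow toward the chord.  (Stating the gradient as pointing
toward the center describes the descent direction, not the gradient; with
fixed endpoints, descent on length must flatten the curve.)

**Shape prior.**  Curves are rescaled to unit length and mapped to the
square-root velocity function q = β̇/√|β̇|, so unit-length curves live on
the unit sphere of L²([0,1],ℝ²) and shapes are orbits under rotation and
reparameterization.  A truncated wrapped normal on the tangent space at the
Karcher mean [μ] gives, for the shooting vector v = exp⁻¹_[μ]([q]),

    E_prior = ½ Σₖ ⟨v,uₖ⟩²/Sₖ + ‖v − ΣₖuₖuₖᵀV‖²/(2δ²),   ‖v‖ < π,

where uₖ are the principal tangent directions, Sₖ the singular values of
the 1/√(n−1)-scaled training shooting-vector matrix (per-mode standard
deviations), and δ = 0.5·min(Sₖ) the tail scale.  The number of retained
modes is the smallest m explaining 95% of variance, capped at 5.

## Discretization and gradients

* Curve derivatives: second-order central differences, one-sided
  three-point stencils at the endpoints; t spacing 1/(T−1).
* Quadrature: trapezoid on the uniform grid.
* Tensor fields: node-centered grid over [0,1]² (node (i,j) at
  ((i+½)/G₁,(j+½)/G₂)), entrywise bilinear interpolation with an eigenvalue
  floor (10⁻⁴ of the largest eigenvalue); the inverse field and the spatial
  gradients of M and M⁻¹ are cached per node (central differences) and
  bilinearly interpolated.  The interpolated gradient cache agrees with
  direct differencing of the interpolated field to ~1% — and exactly when
  the inverse field is bilinear — which bounds the accuracy of the
  data-term gradient on generic fields.
* Data and smoothness gradients are computed as the Euler–Lagrange density
  ∂g/∂β − d/dt(∂g/∂β̇) with d/dt taken by the *same* stencil the energies
  use.  This makes the returned field the exact adjoint of the discrete
  energy at interior samples (endpoint entries are reported but masked by
  the tracker), which is what the finite-difference oracles in the test
  suite verify.
* The prior gradient is the exact vector–Jacobian product through the full
  chain (length rescale → stencil derivative → SRVF map → normalization →
  alignment → log map → quadratic form).  The Procrustes rotation angle is
  differentiated through its 2D closed form φ* = atan2(S,C): the prior is
  not the alignment objective, so its dependence on the fitted rotation
  does not vanish at the optimum.  The log-map adjoint is implemented in a
  cancellation-free form (using ‖q_a − cμ‖ = sin θ) so the gradient is
  well-behaved arbitrarily close to the mean.  An earlier
  perturb-and-reconstruct approximation (step in q, integrate back, divide
  by the step) was abandoned: it produces the *pushforward* J⁻¹w̄ rather
  than the adjoint Jᵀw̄ — a smoothed, preconditioned direction that
  descends the prior alone but is not a gradient, fails finite-difference
  checks, and breaks descent of the combined energy.
* `srvf_to_curve` integrates with the least-squares inverse of the same
  derivative stencil used by `curve_to_srvf`, making the two transforms
  exact mutual inverses up to the stencil's one-dimensional rank
  deficiency.  Fitted means are canonicalized through this round trip so
  the stored mean curve realizes the stored mean SRVF exactly.

## Alignment over the shape orbit

Rotation alignment is closed-form Procrustes.  Reparameterization is a
dynamic-programming search over monotone lattice paths with coprime steps
up to 6 (slopes 1/6…6), alternated with rotation for up to ten rounds; an
exact full-predecessor DP is kept for validation on small grids.  Known
limits, verified in the test suite:

* warps are recovered up to slope quantization of the DP grid (residual a
  few 10⁻²; near-identity warps are not representable exactly);
* a warp like γ(t)=t² annihilates the SRVF at an endpoint (√γ̇ → 0), and
  the lost first-cell mass ~√dt is irrecoverable at any feasible grid;
* because the prior's tail divides by δ², the DP residual is amplified in
  E_prior, so the energy is *not* invariant to reparameterization at the
  10⁻³ level — only rotation/translation/scale invariance is exact.

Inside the tracker the prior therefore uses rotation-only alignment: every
curve entering it is resampled to uniform arc length, making the optimal
warp near-identity, and the rotation-only energy is a smooth function of
the curve, which monotone backtracking requires (the DP warp is piecewise
constant in the curve and makes the energy jump at the 10⁻¹ level).  The
public `e_prior`/`align_shapes` API retains the full alignment.

## The evolution loop

β ← β − δ·P·(λ₁∇E_data + λ₂∇E_prior + λ₃∇E_smooth), endpoints fixed.

* Endpoint entries of the gradient are zeroed *before* preconditioning:
  the descent guarantee needs the masked quadratic form, and the raw
  endpoint entries of the prior gradient are large.
* P is a Sobolev preconditioner (I − τ d²/dt²)⁻¹ with smoothing scale
  0.05 of the parameter interval — an SPD operator that tames the stiff
  high-frequency components of the prior gradient without moving minima.
* Backtracking halves δ until the candidate does not increase E_total; the
  reduced step persists (with ×2 regrowth after accepted steps).  Halving
  is open-ended because the prior term is orders of magnitude stiffer than
  the data term near a straight initialization.
* Each candidate includes a uniform arc-length resampling.  Without it the
  direction-only data term can be gamed by bunching samples along aligned
  segments (a sawtooth that lowers the discrete energy while corrupting the
  geometry); resampling inside the candidate denies that exploit while
  keeping the accepted energy trace monotone by construction.
* Stopping: relative E_total change below 10⁻⁶ for five consecutive
  iterations, a stationary state (no acceptable step), or `max_iter`.

## Synthetic phantoms

Ground-truth fibers are drawn on [0,1]² and rasterized to a 20×20 grid:
each cell's tensor is a_long·(mean outer product of unit tangents of the
segments in the cell) + a_perp·I; untouched cells get iso_baseline·I; all
entries are Gaussian-smoothed (σ = 0.75 cells) and eigenvalue-floored.
Defaults a_long = 1.0, a_perp = 0.1, iso_baseline = 0.2 give white-matter-like
planar anisotropy (~0.89).  ODF phantoms place antipodal von Mises lobes
(sharpness κ = 6) at the segment tangent angles.

The `crossing` scene is the main benchmark: five nearly coincident gently
bowed fibers (bow 0.12 over a 0.8 chord) between two endpoint regions, plus
a second bundle that rises through the apex at 60° and bends into a
roughly horizontal decoy course.  The geometry was chosen so that the three
reconstruction regimes of the reference comparison appear: a deterministic
streamliner is carried through the junction onto the decoy and terminates
far from the target region; the tracker without the prior connects the
endpoints but is locally displaced near the junction; the full tracker
recovers the bundle to a few 10⁻³ domain units.  Training ensembles for
the prior are independently generated jittered arcs from the same family
(30 curves, bow jitter 0.03).

What the green experiment does **not** establish: performance on real
scanner data (noise statistics, partial volume, 3×3 tensors), robustness to
mis-specified priors (training shapes from a different tract family), or
3D behavior.  The phantom's tensors are exact functions of the ground
truth; real tensor estimation noise is only crudely imitated by the
optional additive-noise and noisy-patch mechanisms.

## Evaluation

A reconstructed fiber is scored by the L2 distance to ground truth after
resampling both curves to 100 arc-length-uniform points (truth orientation
chosen by the smaller distance); a bundle score is the mean over fibers,
each matched to its nearest truth fiber.  Distances are in domain units of
the unit square.

## Known limitations

* The printed prior is dimensionally uneven (Sₖ enters linearly, δ
  quadratically); we follow it as stated.  Consequently the tail is sharp,
  which makes E_prior sensitive to any alignment residual (see above).
* The DP reparameterization search is a grid method; its slope
  quantization bounds orbit-invariance to ~3×10⁻² in shape distance.
* Streamline defaults (step ¼ cell, 45° angle threshold, anisotropy floor
  0.15) are conventional choices, not fitted to data.
* Endpoints are strictly fixed; ROI-interior endpoint relaxation is not
  implemented.
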