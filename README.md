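# elastract

Bayesian active-contour tractography on 2D diffusion fields with elastic
shape priors.

## The problem

Estimating white-matter fiber tracts from diffusion MRI is usually done
*locally*: streamline methods such as FACT grow a curve step by step along
the principal eigenvector of the local diffusion tensor.  They are fast but
fragile — at fiber crossings and in noisy regions the local direction is
ambiguous, tracks get diverted or stop, and a tract that anatomically
connects two regions is never recovered.  Tractography is really a
*two-boundary* problem: both endpoints of the tract are known (regions of
interest), and what is sought is the most plausible curve between them.

`elastract` takes the global view.  A fiber estimate β : [0,1] → [0,1]² is
initialized as a straight segment between the two endpoints and deformed by
gradient descent on a posterior energy

    E_total(β) = λ₁ E_data(β) + λ₂ E_prior(β) + λ₃ E_smooth(β)

* **E_data** = ∫ n(t)ᵀ M(β(t))⁻¹ n(t) dt measures the alignment of the unit
  tangent n with the local diffusion tensor M (scale-invariant: direction,
  not speed).  For HARDI data the same role is played by
  ∫ −f_β(t)(n(t)) dt with f the orientation distribution function on the
  circle.
* **E_prior** is the negative log-density of a truncated wrapped-normal
  model on the *elastic shape* of the curve: curves are represented by
  their square-root velocity function q = β̇/√|β̇| on the unit preshape
  sphere, a Karcher mean and principal components are fitted to training
  fibers, and deviations are scored by a Mahalanobis form with a sharp
  tail, ½ v∥ᵀS⁻¹v∥ + ‖v⊥‖²/(2δ²).
* **E_smooth** is the curve length, whose gradient is the curvature flow.

All three gradients are analytic (the prior's via an exact vector–Jacobian
product through the shape-space chain), so the evolution is a plain
backtracked gradient descent with a monotone energy trace.  The package
also contains a FACT streamline baseline, synthetic tensor/ODF phantom
generators, and bundle-distance evaluation.  See `docs/methods.md` for the
full numerical story.

## Worked example

```python
import numpy as np
from elastract import (make_scene, scene_to_tensor_field,
                       make_training_shapes, ShapePrior,
                       BayesianTracker, fact_track, bundle_distance)

scene = make_scene("crossing", seed=1)            # two bundles, one junction
field = scene_to_tensor_field(scene)              # 20x20 smoothed SPD grid
truth = scene.truth_fibers

train = make_training_shapes(make_scene("arc_bundle", seed=10_001), T=100)
prior = ShapePrior(n_points=100).fit(train)       # Karcher mean + tangent PCA

tracker = BayesianTracker(lambda_data=0.8, lambda_prior=0.1, lambda_smooth=0.1)
trajs, _ = tracker.track_bundle([(f[0], f[-1]) for f in truth], field,
                                prior=prior, seed=1)
streamlines = [fact_track(field, f[0]) for f in truth]

print("streamline ", bundle_distance(streamlines, truth).mean)
print("with prior ", bundle_distance([t.final for t in trajs], truth).mean)
```

Output:

```
streamline  0.10926883473006825
with prior  0.002103535010651297
```

The FACT baseline is carried onto the wrong branch at the junction and ends
~0.1 domain units from the truth bundle, while the active contour with the
shape prior recovers it to ~2×10⁻³ — a fifty-fold improvement, with both
endpoints anchored in their regions of interest by construction.  Running
the tracker with `lambda_prior=0` lands in between (~4×10⁻³ here): the
endpoints are right but the shape is locally displaced near the junction.

The same comparison is packaged as
`elastract.evaluation.run_figure5_experiment(seed)` and as the
`reproduce-fig5` CLI subcommand.

## Command line

```sh
elastract simulate --kind crossing --seed 7 -o out/sim      # field + truth
elastract fit-prior --seed 7 -o out/prior                   # shape model
elastract track --field out/sim/tensor_field.nii \
    --model out/prior/shape_model.json \
    --start 0.1 0.35 --end 0.9 0.35 -o out/track            # one evolution
elastract streamline --field out/sim/tensor_field.nii \
    --seeds out/sim/truth_fibers.csv -o out/sl              # FACT baseline
elastract evaluate --estimate out/track/tracked_fiber.csv \
    --truth out/sim/truth_fibers.csv -o out/eval            # distances
elastract reproduce-fig5 --seed 1 -o out/fig5               # full comparison
```

Every run echoes its effective configuration (`config.yaml`) and a log into
the output directory; a single `--seed` fans out to all stages.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the crossing-field comparison from scratch — phantom generation,
prior fitting, streamline baseline, and both tracker variants — printing
the three mean bundle distances, and writes the target report to the given
path.
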