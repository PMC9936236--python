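# Methods

This note records the models in the package, the parameters that matter,
and the design choices made where the design was genuinely open.

## Phantoms

A case is a voxel grid of boolean structure masks: body (cylinder), one
ipsilateral lung (ellipsoid), an ellipsoidal CTV placed peripherally inside
the lung, PTV = CTV + 5 mm isotropic expansion, chest wall (10 mm inner
shell of the body on the lung side), spinal cord / esophagus / bronchus
(z-axis tubes), heart (ellipsoid), five 4 mm-wide rings at 0.3 / 1.0 / 2.4
/ 4.4 / 6.0 cm outside the PTV, and a 1 cm-wide evaluation shell starting
2 cm outside the PTV.  All distances are physical: dilation and erosion
threshold a Euclidean distance transform sampled with the voxel spacing, so
margins are exact in mm at any resolution.  Rings are clipped to the body
contour (dose outside the patient is meaningless).  CTV placement draws are
rejected when the PTV would touch a serial organ — the package models
peripheral lesions, where target and central structures are separated — or
when any ring would come out empty; generation is deterministic per seed.

Two geometry presets exist.  The default grid is 64×64×48 at 2.5 mm with
the ring distances above.  The `small` preset (16³ at 5 mm, rings at
0.2–2.2 cm, CTV radius 4–6 mm) is the smoke-scale geometry used by the
end-to-end tests: the full-size ring system physically cannot fit a 16³
grid, so every distance shrinks proportionally.  DVH and optimization
behavior are resolution-robust, which is what makes the small preset a
meaningful stand-in.

## Dose engine

A deliberately simple pencil-beam surrogate for a commercial optimizer's
dose calculation.  Nine coplanar beams at 40° intervals are decomposed
into 5×5 mm beamlets covering the PTV projection plus a 5 mm margin;
beamlet `b` deposits `exp(-μ d(v)) · exp(-lat(v)²/2σ²)` in body voxel `v`,
where `d` is the in-body path length along the beamlet's central axis
(marched at half-voxel steps) and `lat` the distance from that axis.
Defaults: μ = 0.005 /mm, σ = 3 mm, lateral cutoff 3σ.  No scatter,
heterogeneity or output factors: the adjustment policy only needs a linear,
non-negative dose operator with realistic gradients.  σ was set (together
with the initializer's starting slack, below) so that the achievable dose
gradient is steeper than the predicted one — i.e. ring objectives can be
productively tightened for roughly ten adjustment steps before target
coverage starts to give, which is the regime the adjustment method
presumes.  With a blunter kernel the starting plan already sits at the
achievable gradient and every tightening step immediately trades away
coverage, leaving the policy nothing to learn.

## Objective function and optimizer

The plan cost is the hybrid of one-sided quadratic PTV point terms and
upper gEUD terms for six OARs and five rings (README formula).  Fixed
weights: 300 for both PTV terms, 150 for everything else.  gEUD uses
a = 40 for serial organs and rings (near-max dose) and a = 1 for lung
(mean dose); the generalized mean is computed max-normalized for overflow
safety, and `a = 1` returns the arithmetic mean exactly.

PTV point costs carry the conventional ½ factor and are **summed** over
voxels, not averaged.  This is a deliberate normalization choice: the
target terms then grow with the number of violating voxels while each
gEUD term stays a scalar, so prescription coverage dominates the eleven
gEUD terms the way clinical optimizers prioritize the target.  With
volume-averaged point costs the small-phantom PTV term is so weak that a
single 10% ring tightening costs ~3 Gy of D95 and nearly every adjustment
episode ends immediately in the coverage-breach penalty.

One "optimization pass" is L-BFGS-B over non-negative beamlet weights with
an analytic gradient (maxiter 300, ftol 1e-12).  The cold start scales
uniform weights to put the mean PTV dose at the lower objective; within an
episode each pass warm-starts from the previous weights.  A returned plan
never has a higher cost than its starting point (monotone acceptance).
The budget matters for the reward signal: with looser tolerances,
re-optimizing an unchanged objective set drifts the plan score by tens of
points, which masquerades as real quality change.

## Plan metrics and state

Cumulative DVHs use 850 uniform 0.1 Gy bins spanning 0–85 Gy (1.7× the
50 Gy prescription, covering all hot spots).  The RL state is the 850×12
DVH matrix in canonical order (PTV, Ring1–5, lung, heart, spinal cord,
esophagus, bronchus, chest wall); each ring agent sees the three columns
PTV / body / own ring, so the body DVH is computed alongside the twelve
state structures.  Scalar metrics (D95, Dmax, V5, CI, GI) are computed
from voxel doses directly — D95 as the linearly-interpolated 5th
percentile — not from the binned DVH.  When no voxel reaches the
prescription dose CI and GI are undefined; inside the adjustment loop such
degenerate plans are scored with CI = 0 and GI = the half-prescription
isodose voxel count so the episode can still terminate through the
coverage penalty rather than crash.

## Plan-quality score

Eva(s) is the sum of 14 (piecewise) linear criteria (module docstring for
the exact formulas).  Only PTV D95 is capped (at 100); everything else is
once-linear and may go negative, keeping a learning gradient everywhere.
The per-ring reference dose D_ref defaults to the ring's *initial*
objective value, so ring criteria score improvement over the
patient-specific starting point; fixed references are configurable.  This
D_ref convention is a documented interpretation — the scoring table never
defines it.

## Initial objectives

Three steps: predict a dose, reduce it to DVH curves, read one statistic
per structure off the curves.  The default predictor is a calibrated
heuristic: 1.02× prescription inside the PTV decaying as `exp(-d/λ)` with
distance d to the PTV, zero outside the body.  λ = 13 mm was fitted once,
by log-linear regression, against optimizer-generated reference plans on
default-geometry phantoms (`fit_falloff`).  An optional `learned` mode
fits a gradient-boosted regressor on per-voxel geometric features
(structure label, distance to PTV, depth below the body surface) from
pipeline-generated pairs; it must be trained explicitly and errors
otherwise.  The single-channel structure encoding uses PTV 1.0, heart
0.88, cord 0.75, esophagus 0.63, chest wall 0.5, bronchus 0.43; lung
(0.3) and unlabeled body (0.1) fill levels the scheme leaves open.

Because every non-PTV objective is gEUD-type, the statistic read off each
curve is the gEUD of the predicted dose (a = 40 / a = 1), multiplied by a
1.2 starting-slack factor and floored at 0.5 Gy.  The slack plays the role
of a slightly-loose clinical starting template: the first optimization
meets prescription comfortably and the agents have room to tighten.  PTV
objectives are fixed at 1.04× and 1.35× prescription (52 and 67.5 Gy),
weights 300/150 as above.

## Agents and training

Each ring's Q-network is a numpy MLP: the 850×3 view is average-pooled
along the dose axis by 10, flattened (255), passed through ReLU layers of
256 and 128 units to 4 linear Q-values; He initialization, Adam
(lr 1e-3).  Training minimizes the mean squared double-DQN TD error
(selection by the evaluation network, valuation by the target network);
targets sync every 80 adjustment steps.  Replay is a Sum-Tree per agent
(capacity 4096): new transitions enter at the current maximum priority,
batches of 20 are drawn by stratified priority sampling, and sampled
priorities are refreshed to |TD error| + 0.01.  No importance-sampling
correction is applied.  γ = 0.9.  ε-greedy exploration starts at 0.95,
decays multiplicatively by 0.95 per episode, floors at 0.1 (the
multiplicative reading is the only sensible one — linear subtraction would
exhaust in one episode).

The reward cases are evaluated in their printed order; the
"already-satisfied ring" test compares the *previous* plan's ring gEUD to
its objective before the action, and the coverage test uses the *adjusted*
plan's D95.  Plan-score changes smaller than 1.0 point count as
"unchanged" (+5): surrogate-optimizer jitter is below that level, and
with an exact-equality reading every keep-step would be rewarded by a coin
flip between +20 and −20.  An episode ends at 20 steps (training) or 25
(evaluation) or when D95 drops below 95% of prescription (terminal,
−200 to every agent).

## Evaluation

For each held-out case the greedy policy runs one episode from the
patient-specific initial plan.  The reported "final" plan is the last plan
along the trajectory that still met the coverage floor (a clinic would not
accept a non-covering plan).  For reporting only — never for RL states —
doses are renormalized so the prescription covers 95% of the PTV before
metrics are compared, mirroring clinical plan normalization.  Cohort
comparisons use paired Wilcoxon signed-rank tests (final vs initial per
metric), with the p-value left undefined when all paired differences are
zero.

## Problem sizes in the test suite

The end-to-end experiment trains on three 16³ `small`-preset phantoms for
30 episodes (ε reaches ≈0.2) and evaluates on 20 held-out phantoms; at
these sizes a full train-plus-evaluate cycle takes a few minutes on one
CPU core.  What passing shows: the reward trend rises as the agents learn
when tightening stops paying, and the trained greedy policy improves the
normalized plan score on held-out synthetic anatomy.  What it does not
show: performance on clinical CT anatomy, real beam models, or a
commercial optimizer — the surrogate reproduces the qualitative adjustment
dynamics, not clinical dosimetry; heterogeneity, scatter, motion and
deliverability are all out of scope.

## Known limitations

- The shared plan-score reward gives individual agents a weak
  credit-assignment signal (only the −50 case is purely per-agent); with
  the small training budget the learned policies are serviceable, not
  optimal.
- The DVH state carries no spatial information (hot-spot locations are
  invisible), and the agents do not see the current objective values.
- gEUD curve extraction from binned DVHs inherits the 0.1 Gy bin
  resolution; scale equivariance of the objective initializer is exact
  only up to binning.
- The dose predictor is isotropic in distance-to-PTV and ignores beam
  geometry; it is a starting-point generator, not a dosimetric model.
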