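# moapn

Automatic inverse planning for lung SBRT on synthetic thoracic phantoms:
five double-deep-Q-network (DDQN) agents learn to adjust the five
ring-structure optimization objectives of an IMRT plan, starting from
patient-specific initial objectives derived from a predicted dose
distribution.

## Who this is for

Medical-physics and RL researchers who want a fully self-contained,
desk-scale testbed for *objective-adjustment* automatic planning — the loop
a human planner runs in a treatment planning system: set objectives,
optimize, inspect the plan, tighten or loosen objectives, repeat.  No
clinical data, no commercial TPS: phantoms, dose engine, optimizer, scoring
and agents are all in the package.

## The model

**Plan optimization.** Beamlet weights `w ≥ 0` of nine coplanar 6 MV beams
(40° apart) map linearly to dose through a pencil-beam influence matrix
`A`: `D = A w`, with per-beamlet deposition
`exp(-μ·depth)·exp(-lat²/2σ²)`.  One planning pass minimizes the hybrid
objective

```
min_w   ω_L^PTV Σ(D - D_p)²_lower  +  ω_H^PTV Σ(D - D_max)²_upper
      + Σ_i ω_i^OAR (gEUD_i - D_EUD_i)²_+  +  Σ_j ω_j^ring (gEUD_j - D_EUD_j)²_+
```

with `gEUD = (Σ D^a / V)^(1/a)` (a = 40 for serial organs and rings, a = 1
for lung), weights fixed at 300 (target) and 150 (all other structures),
prescription 50 Gy / 5 fractions.

**Initial objectives.** A dose predictor (exponential falloff with
distance to the PTV, calibrated against optimizer-generated reference
plans) is reduced to dose-volume curves; each ring/OAR objective starts at
the gEUD of its predicted curve (×1.2 starting slack).

**Adjustment policy.** Each of the five rings has a DDQN agent seeing the
850×3 cumulative-DVH state (PTV, body, own ring).  Actions multiply the
ring's `D_EUD` by 0.90 / 0.97 / 1.00 / 1.05.  After all five adjustments,
one optimization pass re-solves the plan and each agent is rewarded from
the plan-quality score Eva(s) (14 additive criteria: PTV D95 / CI / GI,
ring Dmax, OAR Dmax, lung V5): −200 (terminal) if D95 < 95% of
prescription, −50 for raising an already-satisfied ring objective, else
−20 / +5 / +20 as the score falls / holds / rises.  Training uses
ε-greedy exploration (0.95 decaying ×0.95 per episode to 0.1), Sum-Tree
prioritized replay (capacity 4096, batch 20) and target-network syncs
every 80 steps.

## Worked example

```python
from moapn import (GridSpec, GeometryConfig, generate_case, build_influence,
                   initial_objectives, optimize_plan, ScoringConfig, eva_score)

grid = GridSpec((16, 16, 16), (5.0, 5.0, 5.0))
case = generate_case(seed=1, grid=grid, geometry=GeometryConfig.small())
influence = build_influence(case)
objectives, predicted = initial_objectives(case, prescription_gy=50.0)
plan = optimize_plan(influence, case, objectives)
scoring = ScoringConfig.from_ring_objectives(objectives.ring_objectives())
print(f"PTV D95 = {plan.metrics['ptv_d95']:.2f} Gy")
print(f"CI = {plan.metrics['ptv_ci']:.3f}, GI = {plan.metrics['ptv_gi']:.2f}")
print(f"Eva(s) = {eva_score(plan, scoring):.1f}")
```

prints (seed 1):

```
PTV D95 = 52.10 Gy
CI = 1.000, GI = 5.67
Eva(s) = -191.3
```

The initial plan covers the target conformally but spills dose (GI 5.7
against the ≤ 3.75 scoring threshold), so its score starts low — that is
the head-room the adjustment agents are trained to claim.  Training and
evaluating the policy end-to-end:

```python
from moapn import TrainingConfig, train, evaluate

cases = [generate_case(s, grid=grid, geometry=GeometryConfig.small()) for s in (1, 2, 3)]
infls = [build_influence(c) for c in cases]
ensemble, curve, _ = train(cases, infls, TrainingConfig(n_episodes=30), seed=7)
print(curve["cumulative_reward"].iloc[:10].mean(), curve["cumulative_reward"].iloc[-10:].mean())
```

prints `-22.0  59.3`: the per-episode cumulative reward rises as the agents
learn when tightening stops paying.  On 20 held-out phantoms the trained
greedy policy raised the (coverage-normalized) plan score on 20/20 cases
(e.g. seed 104: −62.9 → +234.3 over 25 adjustment steps).

A YAML-driven pipeline (`moapn train --config run.yaml`) and subcommands
`generate`, `init-objectives`, `optimize`, `score`, `evaluate` wrap the
same functions; see `moapn --help`.

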