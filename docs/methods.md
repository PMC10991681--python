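# Methods

## The model

`aidriver` simulates a driver agent that selects actions by minimizing
expected free energy (EFE) over a receding horizon. The agent's
environment is a discrete-time POMDP: hidden state `s` evolves under a
known transition model `P(s'|s,a)`, and the driver receives a
deterministic observation `o(s)` in which some dimensions may be
unobservable (null-coded) depending on geometry (an occluded pedestrian)
or the driver's own gaze (the road ahead while looking at a secondary
task).

Goals are priors over observations `P(o)`. A candidate policy
`π = a_{t:t+H−1}` is scored

    G(π) = Σ_τ [ −pragmatic_τ − epistemic_τ ]

with the pragmatic value the expected log probability of the predicted
observations under the preference priors, and the epistemic value the
expected information gain of the predicted observations, computed as
posterior-predictive entropy minus expected ambiguity. Goal pursuit and
uncertainty resolution therefore compete in a single currency: slowing
down for a possibly-hidden pedestrian, moving to gain a sightline, and
glancing back at the road are all consequences of the same objective.

Three approximations make this computable:

1. **Belief = particle ensemble.** `Q(s)` is N weighted particles.
   Updates use sequential importance resampling: propagate through the
   transition model under the executed action, reweight by the
   observation likelihood, systematically resample when the effective
   sample size `1/Σw²` falls below N/2. Because the observation maps
   are deterministic, the likelihood uses a narrow Gaussian kernel
   (`sigma_obs`, native units) on continuous dimensions and exact match
   with a −1000 log floor on discrete/null-coded dimensions. A
   regularised effective-sample-size form `N/(1+Σw²)` is also exposed;
   note its range is [N/2, N], so it cannot serve as a resample trigger
   and the filter uses the standard `1/Σw²`.
2. **Predictions = rollouts.** For each candidate policy, Ñ particles
   drawn from the belief (systematic, low-variance draw) are propagated
   open-loop through the transition and observation models. No belief
   update happens inside a rollout; the value of future observations is
   captured purely by the epistemic term.
3. **Policy search = cross-entropy method.** Mixed continuous/discrete
   action sequences are sampled from a factorised distribution
   (per-step Gaussians / Bernoullis), scored by EFE, and the
   distribution is refit to the elite fraction; the executed action
   comes from the distribution of elite first actions.

## The entropy estimator and the epistemic scale

The posterior-predictive entropy is estimated by a leave-one-out
Gaussian KDE over the scenario's epistemic observation dimensions
(pedestrian position + context observation in scenario 1; vehicle pose
x, y, θ in scenario 2), with unobservable entries encoded by the numeric
null code −1000 so the estimator sees plain vectors.

Estimator choices that matter:

* **Robust bandwidth.** Scott's rate `n^(−1/(d+4))` on the scale
  `min(std, MAD/0.6745)`. A plain standard deviation would make the
  bandwidth — and hence the "entropy" — grow with the ~1000-unit
  separation between null-coded and physical clusters; with the robust
  scale, a present/absent mixture contributes its cluster (Bernoulli)
  entropy, which is the information actually at stake. The MAD is used
  rather than the IQR because its 50% breakdown point keeps the
  bandwidth pinned to the majority cluster for any minority fraction
  below one half.
* **Bandwidth floor 0.2 native units**, acting as a perceptual
  resolution: dispersion below ~0.2 m (or rad) carries no
  distinguishable information.
* **Saturating kernel.** Squared normalised pairwise distances are
  clamped at `4·log(n−1)`, so an isolated sample contributes at most the
  discrete surprise of a once-seen outcome (~`2·log(n−1)` nats above the
  floor) instead of an unbounded squared-distance term.
* **Ambiguity constant.** With deterministic observations the expected
  ambiguity is the entropy the estimator assigns to a perfectly
  degenerate sample set (`d·(½log 2π + log h₀)`). Subtracting it makes a
  degenerate belief score exactly zero epistemic value and any dispersed
  belief a nonnegative value.
* **Epistemic precision.** Differential entropy is unit-dependent, so
  the absolute scale of the information gain is a modelling choice, not
  a derived quantity. An explicit precision weight multiplies the gain:
  10 in the time-sharing scenario (putting the lane-scale crossover
  where the printed gaze preferences of −7…−10 operate) and 18 in the
  occlusion scenario (whose gain is a bounded discrete-context cluster
  entropy of ~0.5 nat per step). Only orderings of epistemic values are
  treated as meaningful.

## Planner details

Defaults: M = 64 samples, K = 3 iterations, elite fraction 0.1,
Ñ = 32 planning particles (reduced profile: 32 / 3 / 0.25 / 16; N
particles 1024 / 256). Numerical choices that proved load-bearing at
these sample counts:

* **Correlated exploration.** Policy noise is AR(1) across the horizon
  (ρ = 0.9). Sustained inputs are what distinguish good from bad
  policies for slow (integrating) dynamics; i.i.d. per-step noise gives
  elite selection no usable signal.
* **Noise schedule.** The sampling std decays geometrically (×0.5) per
  iteration from per-dimension initial values (wide for longitudinal
  acceleration so braking can be discovered; narrow for steering rate
  and lateral acceleration). Wide steering exploration would make most
  sampled rollouts exit the lane at speed — an effect growing like v² —
  and the planner would slow down to protect itself from its own noise.
* **Nominal proposal (lane keeping only).** In the time-sharing
  scenario the first iteration's mean is a nominal stabilising sequence
  (cascaded lane-centering plus proportional speed keeping) rolled out
  on the belief-mean state, recomputed from scratch every control step.
  This supplies steering authority that per-step exploration noise
  cannot, including blind heading stabilisation during off-road glances.
  It is not a warm start: nothing carries over between steps.
* **Executed action.** Continuous dimensions execute the mean of the
  elite first actions (sampling them would inject exploration noise far
  above the scenarios' physical disturbances); discrete dimensions are
  sampled from the raw elite frequencies, so a unanimous gaze choice is
  deterministic. The discrete sampling probability is initialised at
  the gaze preference prior and clamped to [0.02, 0.98] inside the
  iterations.
* Conflict is treated as absorbing along a rollout once the pedestrian
  safe distance has been violated (a collision does not un-happen);
  lane-edge crossings are recoverable and flagged per step.

## Scenarios

**Occlusion (scenario 1).** Point-mass ego on a 3 m lane, speed limit
10 m/s, dt 0.2 s, 4 s horizon, 10 s episode. Sight corner (28, −1.8) m,
pedestrian site (32, −3) m, safe distance 2 m: a centred ego gains the
sightline at x = 22 m, and the line-of-sight boundary is
`x_LOS(y) = 22 − (10/3)·y`. Ground truth never contains a pedestrian;
the belief starts at p(present) ∈ {0, 0.2} by variant. Preferences:
speed N(10, 1); longitudinal comfort N(0, 1); lateral comfort N(0, 2)
and triangular lane keeping (variants with lateral freedom); absolute
no-conflict (−1000 planning floor, −100 when exporting plotted values).

A geometric bound worth recording: with the straight-line sight
distance pinned at 22 m and the conflict zone at the site, the
line-of-sight slope dx/dy cannot exceed 10/3 in this layout, so the
largest in-lane lateral excursion (~1.2 m) buys at most ~4 m ≈ 0.5 s of
earlier visibility at the braked approach speed. The lateral variant
therefore resolves the uncertainty about half a second before the
straight-only variant (median 2.6 s vs 3.0 s over ten seeds) rather
than a full second, and the EFE margin of a large lateral dart (an
extra one or two beyond-sightline lookahead steps versus the triangular
lane-keeping dwell cost) is thin enough that the executed excursions
stay small.

**Visual time-sharing (scenario 2).** Kinematic bicycle (wheelbase
2.7 m, wheel angle ≤ 0.5 rad) on a straight lane of width 3 m (narrow
variant 2.5 m), 30 s episodes, steering-rate disturbance
N(0, 0.001 rad/s) per step in both the generative process and the
agent's rollouts. Gaze is a binary state set deterministically by a
binary action; off-road glances null-code x, y, θ while wheel angle,
speed, inputs and the lane-crossing (rumble strip) flags stay
observable. Preferences: speed N(10, 1); triangular lane keeping
(masked while off-road); comfort N(0, 1 m/s²) and N(0, 0.05 rad/s);
normalized Bernoulli gaze prior (log p(on-road) = 0 baseline, −7
default, −5/−10 sweeps); absolute no-lane-exit priors. The observation
kernel `sigma_obs = 0.025` makes a single on-road glance collapse the
lateral belief well below 0.05 m.

## What the simulations do and do not show

All data are generated by these two closed-loop simulations; there is
no external data. The generative process is the same model family the
agent plans with (exactly matched dynamics and noise), so passing tests
demonstrate that the stated behavioral patterns emerge from EFE
minimization under matched models — not that the model predicts human
drivers. Real visual time-sharing involves peripheral vision, task
structure, and response latencies that are deliberately out of scope;
on-road glances here last a single 200 ms step by construction.

Problem sizes used by the test suite and the acceptance script: the
reduced agent profile (N = 256, Ñ = 16, M = 32, K = 3, elite fraction
0.25), ten seeds per condition, full-length episodes (10 s / 30 s).

## Degenerate inputs and edge rules

* Zero-density prior evaluations (triangular bounds, degenerate
  Bernoulli) return the −1000 floor, never −inf.
* A belief–observation total conflict (all likelihoods at the floor)
  resets the weights to uniform with a logged warning; so does a
  non-finite or zero posterior weight sum.
* Entropy of fewer than two samples is defined as 0; the estimate is
  clamped below at −10 per dimension.
* The elite refit floors the standard deviation at 0.002 and clamps
  discrete probabilities to [0.02, 0.98]; if every sampled policy
  scores identically, the planner warns and samples from the unrefined
  distribution.
* Runs are reproducible from (config, seed): one seeded generator
  drives the environment, another the agent, both spawned from the run
  seed.

## Known limitations

* The epistemic precision and bandwidth floor are calibrated constants;
  magnitudes of epistemic value are not comparable across estimator
  settings, and no learning of parameters is attempted.
* The CEM planner at desk-scale sample counts remains a noisy
  optimizer: executed behavior carries small action jitter, and rare
  belief-conflict resets occur at glance-end in the time-sharing
  scenario when the true pose lands in the far tail of the belief.
* The lateral epistemic excursion in the occlusion scenario is
  structurally weak under the canonical geometry (see the bound above);
  earlier uncertainty resolution with lateral freedom manifests mainly
  through maintained approach speed.
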