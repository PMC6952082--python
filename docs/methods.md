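# Methods

## Model

An agent flies at constant speed v (default 2 m/s) in the plane; its state
is a discretized pose (x, y, ω) plus the last q control actions, and its
only control is the heading change applied at each step of length dt
(default 0.25 s, i.e. 0.5 m of travel — about two cells of the default
0.25 m planar grid; the grid default of 72 heading bins gives 5° headings).
The action set holds 2m+1 desired headings spanning the π/2 visual arc
symmetrically (m = 2 by default, so offsets −π/4 … +π/4 in steps of π/8).
The commanded turn is applied at the start of the step and the agent then
translates along the new heading (a midpoint-integration option exists).
Continuous endpoints are snapped back onto the grid stochastically —
bilinear area-overlap weights over the four nearest planar cells, nearest
bin in heading with half-to-even rounding of the bin offset so left and
right turns stay symmetric.  This snapping is what turns the deterministic
kinematics into a probabilistic transition model; the induced noise is
O(cell size) per step.  Bounded forests reflect at the walls, periodic
forests wrap.

## Features and the policy class

The policy is a Boltzmann distribution over the linear scores θ′φ(x, u).
Features, per candidate action u:

* **OSD** — each tree within the fog-limited perception range projects to
  an angular interval of half-width arcsin(r/d); intervals narrower than
  the angular resolution (default 0.01 rad) are discarded, the rest are
  unioned exactly (sorted sweep), and the coverage of each of the 2m+1
  segments is the covered fraction of its width.  Occlusion is treated by
  union: a near tree does not hide a far one.  Perception range is
  c_vis/fog with c_vis = 133.2, so the standard evaluation fog 6.66 sees
  20 m; fog 0 means unlimited range.  The fog level is quoted variously as
  6.6/6.66/6.67 in different places; one configuration value covers them.
* **OSD(0), OSD(0.5)** — indicators of coverage strictly greater than 0 and
  0.5 ("more than a fraction p" is read strictly, so an empty segment gives
  OSD(0) = 0).
* **OF** — the 1-D gradient-based optical-flow estimate
  s(u) = (f_prev(u) − f_curr(u)) / (f_prev(u+1) − f_prev(u)) between the
  previous and current OSD signals, last entry copied from its neighbour,
  zero where the spatial gradient vanishes (no texture ⇒ no measurable
  flow).  For affine signals the estimator recovers an integer shift
  exactly; in sparse scenes it is heavy-tailed (near-zero denominators),
  which matters for feature scaling (below).  At an episode start OF = 0.
* **History** — the smoothness term.  The state carries the mean signed
  offset of the last q actions (q = 1 by default; at episode start the
  history is padded with the straight action); the per-action feature is
  |offset(u) − mean|, so a negative weight prefers turns close to the
  recent ones, i.e. smooth flight.  A feature constant across candidate
  actions would cancel in the softmax and its weight could never be
  identified from demonstrations — this is why the per-action deviation
  form is used; the reference moth policy carries a large negative history
  weight, which is only meaningful under an action-dependent reading.
* **Energy** — |offset(u)|: straight flight is free, turning costs in
  proportion to the commanded turn (the proportionality constant is
  absorbed into θ).

### Normalized-weight policies

Policies regressed on standardized features carry the per-feature scale in
their file (`meta.feature_scale`); because mean subtraction is constant
across candidate actions it cancels in the softmax, applying such a policy
to raw features is exactly θ/scale (`PolicyParams.effective_theta`).  The
bundled reference policies use a scale estimated once by a frozen protocol:
per-feature standard deviations over 20,000 uniform-policy decision epochs
(all candidate actions pooled) in a synthetic analog of the experimental
forest — 100 trees of diameter 0.0811 m placed uniformly at random in
139.98 × 139.69 m, fog 6.66, seed 20200109.  This analog is a synthetic
stand-in for the unavailable source-dataset statistics and is labelled as
such in the policy files.  The OF scale (≈ 28) is dominated by the
estimator's heavy tail, which effectively down-weights OF for the bundled
policies; this is a known consequence of the ratio estimator, not a tuned
choice.

## One-step reward

g(x, y) = Σᵢ f(dᵢ/rᵢ) over trees i, where dᵢ is the distance to tree i and
rᵢ its stored size (taken as the diameter by default; a `size_is_diameter`
flag supports radius-valued files, which also controls the projection
radius used by OSD).  The profile f is the unique cubic through
(0, −0.1), (α, 0), ((α+γ)/2, P), (γ, 0) with γ = β/sin(π/72), set to zero
beyond γ; the expected sign structure (≤ 0 inside α, ≥ 0 on [α, γ]) is
verified on a 10⁴-point grid at construction and violations raise.  The
field is then normalized piecewise-affinely into [−0.1, 1]: negatives
scaled so the floor is exactly −0.1, positives so the cap is exactly 1,
zero fixed — a single affine map would shift the zero set that separates
"avoid collision" from "seek cover".  Defaults α = 1, β = 1, P = 43.5.
Note that in dense forests the tiled positive contributions (γ·r can span
many cells) can swamp the negative cores entirely, leaving a nonnegative
field; the [−0.1, 1] range is attained whenever both signs are present.
Rewards depend on position only, never heading.

## Estimation from demonstrations

The demonstration likelihood is the multinomial logistic NLL; the fitted
objective adds λ‖θ‖₁.  The nonsmooth program is solved exactly by the
θ = θ⁺ − θ⁻ split with box-constrained L-BFGS-B (ftol 1e−12, gtol 1e−10);
coordinates below 1e−8 are snapped to zero.  λ_max = ‖∇NLL(0)‖_∞ closes
the path; the default grid is 30 log-spaced penalties down to 1e−5, fitted
warm-started in decreasing λ order, with an 80/20 record-wise random
train/validation split (source tags are retained so grouped splits remain
possible).  Near-flat directions of the likelihood leave the weights
determined to about 1e−3 even when the objective is solved to 1e−10; path
monotonicity should be judged at that tolerance.

The demonstration generator simulates a known-θ policy, upsamples each MDP
step into a fixed-rate continuous log (linear position interpolation, turn
at the step start, optional Gaussian positional jitter, one terminal frame
so the last action stays inferable), and the discretizer inverts it: snap
poses to the grid, infer each action as the heading change to the next
kept frame quantized to the nearest commanded offset (out-of-arc changes
clamp to the extreme action and are counted), and recompute features per
candidate action.  With zero jitter at the MDP rate the round trip is
exact.  The subsampling factor from log rate to MDP step is always
explicit, never defaulted silently.

The standard identifiability benchmark uses a dense periodic forest
(4 × 3 m cell, 0.5 m trees) under heavy fog (26.67 — one of the recorded
experimental fog levels; perception ≈ 5 m), chosen so that every feature
varies in the data: about half of all segments carry coverage, a fifth
exceed the 0.5 threshold, and both thresholds differ across candidate
actions in most states.  In sparser or visually saturated scenes the
indicator features degenerate (all-zero or all-one across actions) and
their weights become weakly identified or unidentifiable.  Under the
benchmark, 2×10⁴ decisions recover a 6-weight ground truth to max abs
error ≈ 0.02–0.05, and the error decreases with sample size.  Passing
these tests shows the estimator is consistent for data generated by the
model itself; it says nothing about model misspecification in real flight
data.

## Actor-critic refinement

The critic tracks the average-reward estimate a, an eligibility trace
z ← ρz + φ(x_k,u_k) (ρ = 0.99 default; 0.9 recommended for fast-mixing
small problems), and least-squares statistics
b ← b + ζ[(g − a)z − b], A ← A + ζ[z(φ_{k+1} − φ_k)′ − A] with ζ_k = 1/k,
the update lines applied sequentially in that order, each reading the
values already updated above it.  The temporal-difference fixed point
E[zδ] = 0 gives the critic weights as r = −A⁺b; the solve is a
minimum-norm least squares (relative singular-value cutoff 1e−6) because A
is rank-deficient at start-up and stays singular along any direction that
scores all state-action pairs equally — a plain regularized inverse blows
the irrelevant constant component of r up against that near-null space.
The actor ascends θ ← θ + η Γ(r) (φ′r) ψ with the score
ψ = ∇θ ln μ(u|x;θ), both φ and ψ evaluated at (x_{k+1}, u_{k+1}), using
the critic state from *before* the current transition is absorbed: r must
be independent of the u_{k+1} draw or the estimator acquires a bias.  Γ
clips to D/‖r‖ when ‖r‖ > D (D = 10), and η_k = c/(k ln k).

Numerical choices: the actor waits out a 1000-step critic burn-in (early r
is meaningless) and its schedule counts from activation; the θ-change
stopping rule compares checkpoints 500 steps apart (a single stochastic
update can be arbitrarily small) after a burn-in, with threshold ε = 1e−4;
a divergence guard aborts when ‖θ‖ exceeds 1e6.  The step-size constant
defaults to c = 50, calibrated once on the 16 × 12 m forest so the actor
makes visible, stable progress within the default 2×10⁴-step budget
(c ≈ 100 destabilizes there); it is the main knob to adjust per problem
scale.  On an enumerable two-state chain the refined policy reaches within
5% of the brute-force optimal average reward, and with the actor frozen
the critic's a converges to the policy's exact value within 2%.

The multi-restart protocol reruns the refinement from independent seeds,
ranks runs by the critic's final average-reward estimate, re-simulates the
top k candidates and returns the winner; the initial average-reward
estimate a₀ is shared across restarts (one pilot simulation of θ₀).

## Evaluation

Exact policy evaluation marginalizes the chain onto planar cells: headings
are integrated uniformly, the previous control is drawn from a supplied
law (default: the policy's own empirical action distribution from a
fixed-seed pilot simulation, standing in for "distributed as the data"),
and the previous pose needed by the optical-flow feature is reconstructed
by reversing the forward snapping stencil and averaging the action
distributions over the candidate previous cells.  The resulting sparse
kernel (stencil-structured for periodic forests) has a unique stationary
distribution for every finite-θ Boltzmann policy (strong connectivity is
asserted); it is solved by a sparse eigen-solve polished by power
iteration to residual 1e−10, and the expected average reward is Σ π(c)
g(c).

The uniform-heading reduction is exact for feature-blind policies (checked
against simulation under θ = 0) but biased for policies that correlate
heading with position: for the bundled moth policy on the 16 × 12 m forest
the bias is a few percent (within simulation error at moderate lengths),
while for near-deterministic tree-orbiting policies it understates the
simulated reward severalfold.  Comparisons between such policies therefore
use long independent simulations (batch-means standard errors, since the
chain is autocorrelated); the reduced chain is the right tool for smooth,
weakly heading-correlated policies and for exact invariance checks.

## Cross-density robustness protocol

For each elementary-grid size n, the actor-critic is restarted from the
bundled moth policy (default protocol: 20 restarts of 2×10⁴ steps, top 3
re-simulated) and both the winner and the moth policy are evaluated by
2×10⁵-step simulations; the reported quantity is the relative shortfall
100·(R_best − R_moth)/R_best per forest.  In this synthetic reconstruction
the per-forest optimizer reliably discovers orbiting specialists that
circle the single tree inside the positive reward annulus, and the
transplanted reference moth policy — whose weights were regressed against
the real dataset's feature distribution, which is not reproducible here —
trails them by well over the 30% margin reported for the original
real-data policy (the gap grows as density falls and the annulus occupies
a vanishing fraction of the area).  The protocol and threshold are kept
as-is; the robustness bound should be read as a property of the original
data-derived policy in its own environment, not of the printed weight
vector transplanted onto synthetic feature statistics.

## Known limitations

* The bundled policies' feature scale is a synthetic reconstruction; all
  conclusions involving the reference weights inherit that caveat.
* The reduced-chain evaluator assumes uniform headings and a q = 1
  previous-control law; use simulation for heading-correlated policies.
* The OF estimator is first-order and heavy-tailed; it is exact only for
  affine signal translations.
* Trees are discs, the world is 2-D, and the dynamics are massless
  kinematics; none of the torque-meter apparatus is modelled.
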