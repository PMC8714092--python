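# Methods

## The foraging world

The model is a discrete patch-leaving problem. On entering a patch the
agent faces `n_objects` (default 9) objects ranked by expected value; the
environment label `env` (default 5 levels) is drawn uniformly per patch.
Object `i` (1-based) rewards with probability
`p_max(env) · 2^(−τ(env)·(i−1))`; a delivered reward has integer size 1–5
drawn from the environment's size distribution (uniform by default), and a
miss reveals size 0. Behavior has two phases: inspection (reveal the
next-best object at cost `t_inspect` = 0.5 s per object) and consumption
(consume revealed rewards largest-first at `t_consume` = 1.25 s each), then
travel (`t_travel` = 8 s) to a new random patch. A reward consumed `t`
seconds into the patch is worth `r·(1−k)^t` with `k` = 0.275 per second
(half-life ≈ 2.2 s), modeling interruption risk; the time parameters mirror
the analogous intervals of the visual-search task.

The MDP state is `(env, N_inspected, r)` where `r` is the non-increasing
multiset of revealed sizes including zeros. With 6 possible sizes the state
count is `n_envs · Σ_{n=0..9} C(n+5, 5)` = 25 025 at the defaults. The
enumeration only ranges over sizes producible under the configuration
(`size_support`), so degenerate worlds (e.g. a single reward size) get
proportionally smaller state spaces.

## Solving for the optimal policy

Action values are reward rates over a fixed horizon `T_max`
(= the maximum patch duration, 23.75 s by default). The consumption value
maximizes over how many of the `i` biggest revealed rewards to consume,
crediting the discounted rewards plus the global rate `R_global` earned
over the horizon time remaining after travel; the inspection value is the
transition-weighted mean of successor values. The DP runs backward over
`N_inspected`. Since `R_global` is itself policy-dependent, the solver
iterates: solve the DP at the current rate, then re-evaluate the resulting
policy's true rate *exactly* by forward propagation of state probabilities
(expected discounted reward per patch over expected patch time including
travel). Exact evaluation rather than simulation keeps the fixed-point
iteration deterministic; Monte-Carlo simulation exists only as an
independent check. Iteration stops when the policy is unchanged **and**
|ΔR_global| < 1e−6 reward/s, capped at 40 iterations (non-convergence is
flagged on the result, not raised); on the reference configuration it
converges in 4. At the fixed point the mean fresh-patch value over
environments equals `R_global` (algebraically implied by the horizon
normalization), which the tests verify.

Tie-breaking: equal action values resolve to consume-and-leave, and the
greedy consumption count prefers the smaller count on ties; any consistent
rule is value-equivalent. Threshold extraction verifies that within every
(environment, inspection-count) slice the decisions are separated by a
single consumption-value threshold (tolerance 1e−12) and reports the
midpoint between the largest inspect-state and smallest consume-state
consumption values; one-sided slices (e.g. the single state at
`N_inspected` = 0) report the finite side's value. Consequently the
monotonicity claims (thresholds falling with inspections, rising with
richness) are statements about the populated slices `N_inspected ≥ 1`.

## Information-restricted policies

Four observability settings are solved: P1 sees only the inspection count,
P2 adds the environment, P3 the revealed rewards, P4 the full state. All
decisions — inspect-vs-consume *and* the consumption count — condition only
on the observable features; hidden components are marginalized under the
exact belief. Because the inspection order is fixed and a restricted policy
acts identically across states sharing its observable signature, the belief
at a signature is policy-independent: a uniform prior over environments
times the forward reach probability of each revealed multiset under
inspection. The same quantity is exposed analytically as
`belief_posterior`: a Poisson-binomial likelihood of the success count over
the index-dependent reward probabilities times the multinomial likelihood
of the observed size multiset, normalized across environments; the tests
check it against the forward-propagated occupancies. Backward induction
with belief-weighted action selection at each signature is exact here
because signatures form a tree indexed by the inspection count.

This strict reading (reward-blind policies may not even use the revealed
rewards when choosing how many to consume) reproduces the qualitative
signatures: P1/P2 never inspect more than two objects in the forced-outcome
probe, P3 behaves identically in all environments, and in the null variant
E the full policy collapses onto P3 state-by-state.

## Environment variants

Variant A is the reference (`p_max` = 0.1…0.9, τ = 0.7). Variants B–D
realize richness through the decay rate, the reward-size distributions, or
a combination; their qualitative descriptions do not pin down numeric
values, so the presets store documented provisional choices and return
plain configs the caller can edit:

* **B** — shared `p_max` = 0.9, τ = (2.8, 1.6, 0.9, 0.5, 0.25): richer
  environments deplete more slowly.
* **C1** — shared decaying probability (`p_max` = 0.5, τ = 0.7) with
  exponentially tilted size distributions, weights ∝ `exp(β(m−3))`,
  β = −1…+1 across environments.
* **C2** — as C1 but with a constant (non-decaying) per-object probability,
  set to 0.2 so that inspection counts in the probe do not saturate at the
  9-object ceiling in rich environments.
* **D** — A, B and C1 combined, each varied by one third of its extent
  (`p_max` ± 0.133 linearly; τ spanning a third of B's extent in octaves
  around the geometric center; β = −1/3…+1/3).
* **E** — the null: constant probability 0.5, a single reward size 3,
  identical environments.

The search-task probe forces outcome sequences (reward condition: first
reveal = 3, later reveals = 0; no-reward: all 0) rather than conditioning
on rare sampled trajectories — the deterministic equivalent of examining
the policy on trials where those outcomes occurred. The probe reward size 3
is the median of 1–5.

## Task geometry and gaze processing

Screen coordinates are degrees of visual angle, screen-centered, +x right,
+y up, ring rotations counterclockwise. Twelve environmental fractals sit
in three radially symmetric rings (6° eccentricity rotated −22.5° from the
cardinal axes; 15° rotated +22.5°; 17.5° rotated −22.5°), targets at 12°
eccentricity at 40/130/220/310°, and the start cue at the center. Gaze
windows are the 77 nearest bins on a 100×100 grid over a 61°×61° square
(bin edge 0.61°; the window is ≈ a 3°-radius circle). The environmental and
start windows are mutually disjoint and this is asserted at construction;
each target window, however, shares 5 bins with the nearest middle-ring
window (centers 5.07° apart), so sample assignment uses the priority
target > start > environmental > other. Invalid (blink) samples count as
"other"; the four components always sum exactly to the search duration.

Saccade detection resamples to 1-ms spacing by linear interpolation
(interpolating across invalid spans), differentiates, smooths speed with a
15-ms moving mean, thresholds at 0.025°/ms, and discards movements under 1°
amplitude. Direct initial saccades end within 1.5° of the target center;
trials with blinks during the initial target foveation should be excluded
from direct-saccade analyses upstream. The "remaining search after a broken
direct fixation" measure uses the first sample outside the 1.5° target zone
as the moment gaze left the target — the minimum-dwell criterion is
otherwise unspecified, and this is the simplest consistent choice.

## Behavioral statistics

ROC areas use the rank (Mann-Whitney) formulation with half credit for
ties; Spearman correlations use midranks with two-sided permutation
p-values `(1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1)` (default 10 000
permutations). Bootstrap CIs are equal-tailed percentile intervals; the
resampling unit is the trial (session-level clustering is not modeled — a
known limitation). Condition means are taken over the 8 realized
(target value × environment probability) combinations; a component's share
of reward-related variance is the percentage drop in condition-mean
variance after subtracting it from the total, so shares may sum above
100%. OLS fits use main effects of p(reward) and the 0/1 reward value
only. The RRR divides the achieved rate
`E[reward|correct] / (E[post-array time|correct] + E[errors per correct]·E[post-array time|error])`
by the counterfactual rate in which the no-reward trials' mean correct
search duration and error-per-correct ratio are replaced by the reward
trials' values, keeping the actual correct-trial mix. Repeat trials are
included in duration analyses.

## The synthetic-session generator

The generator emulates the task structure the analyses assume: five
environments with reward probabilities 0/25/50/75/100%, ~25% interleaved
single-fractal trials, a 5-s search cap with a 0.75-s terminal hold, a
0.5-s outcome delay and 1–2-s inter-trial intervals, and search errors that
repeat the condition on the next trial. Total search durations are
truncated log-normal (positive and right-skewed) with linear effects on the
log scale: a negative target-value effect (−0.65), a positive
environment-probability effect (+0.5), σ = 0.45 and baseline log(0.8) —
sized so the ROC between no-reward and reward durations sits near 0.73,
echoing the discriminability scale of the search task it emulates. The
non-environmental gaze components have small condition-independent
baselines; the condition-driven remainder of the duration loads on the
environmental-fractal component (or on target dwell in direct-saccade
trials, whose probability falls with environment probability on no-reward
trials). Search-error probability is 2% on reward trials plus 8% on
no-reward trials. The RRR implied by these parameters has a closed form
(`GroundTruth.expected_rrr`), computed on the stationary trial distribution
with the repeat-until-correct reweighting `1/(1−p_error)`; the pipeline
estimate converges to it as the session grows.

Gaze traces render a fixation plan at 1 kHz: per-fixation Gaussian offsets
plus a slow AR(1) wander (ρ = 0.97, SD 0.15° by default — far below the
velocity threshold after smoothing), and 25-ms smooth-step saccades whose
peak velocity (1.5 × amplitude / duration) exceeds the detection threshold
for amplitudes above ~0.5°. Environmental dwell is split across 1–6
fractals with a floor of half the equal share, keeping planned fixations
above the 50-ms inspection criterion. Saccade kinematics are schematic:
only detectability matters for the round-trip tests, not main-sequence
realism. Because saccade deceleration spends a few tens of milliseconds
inside the destination window, measured dwells slightly exceed planned
ones; round-trip tests use tolerances of that order. The generator does not
model the precue epoch, pupil dynamics, microsaccades or oculomotor
biomechanics, and passing round-trip tests shows the pipeline recovers the
generator's structure — not that real eye data are this clean.

## Problem sizes and determinism

Everything is deterministic given a seed. The solver handles the 25 025-
state reference world in well under a second per policy, so the test suite
solves all variants directly. Simulation-based checks use sizes chosen for
tight-but-cheap inference: 30 000 Monte-Carlo patches (3-SE agreement with
the exact rate), 100 synthetic sessions of 2000 trials for sign-recovery
(≥95% criterion), and 120 null sessions of 300 trials for permutation-test
calibration. Brute-force policy enumeration is restricted to worlds with
two environments, two objects and binary sizes (~236 000 deterministic
policies).
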