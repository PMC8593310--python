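# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, and what the simulations
do and do not show.

## Driving as a bounded-road POMDP

The hidden state is the car's lateral offset `x` (meters from the center
of the middle lane of a three-lane, 3.5 m-per-lane carriageway). Speed is
fixed per condition. The action is the *absolute* steering-wheel
position, one of `{−0.1, −0.03, −0.01, 0, 0.01, 0.03, 0.1}`
(dimensionless); the wheel is held between decisions. One driving cycle
of `dt = 0.25 s` advances

    x' = clip( x + v·dt·a + drift·dt + v·dt·ε ,  ±3.5 m )

with `ε ~ N(0, σ_d²)`, `σ_d = 0.03`. Three modelling commitments matter:

* **Noise rides on the action.** Steering-execution noise has lateral
  effect `v·dt·σ_d`, so control error grows with speed — the mechanical
  reason the 120 km/h condition is less stable (lateral SD per cycle
  0.125 m at 60, 0.25 m at 120). A speed-independent additive noise could
  not produce this.
* **The road is bounded.** ±3.5 m is the outer edge of the carriageway
  (also the belief's support); beyond it the car rides the edge. Without
  this, excursions leave the representable state space and recovery
  control collapses.
* **Lane deviation is a body crossing.** The deviation threshold is
  `(lane_width − car_width)/2 = 0.85 m` (car width 1.8 m). With a point
  car the 1.75 m margin makes deviations essentially impossible at
  realistic offsets and removes the safety pressure entirely. Setting
  `car_width_m = 0` restores the point-car convention.

Out-of-lane time is penalized at 10 per second — sized so a typical
deviation wipes out a large share of one search task's +10 gain, keeping
the instructed priority ("keep the car centered") binding. The road
drifts 0.02 m/s leftward (the gently bending highway).

The agent sees only a discretized observation (21 bins over ±3.5 m):
correct with probability 0.9, otherwise a uniformly random other bin. A
Bayes filter combines a *learned* prediction model τ_d — empirical
next-bin frequencies from 60 000 fully observed random-action steps,
with an identity-plus-diffusion fallback (ε = 0.05 to each neighbor) for
unvisited rows — with that likelihood. The policy state is the belief's
sufficient statistic: (argmax bin, entropy binned into 8 equal widths
over [0, log 21]); ties in the argmax break to the lowest index, entropy
is in nats with 0·log 0 ≡ 0.

The lane-keeping policy trains for 20 000 (full) / 4 000 (fast) episodes
of 120 cycles. Two curriculum devices give the Q-table coverage of the
states blind driving will visit under the supervisory model: occlusion
*bursts* (observations withheld for geometric stretches, mean 8 cycles,
occasionally 3× longer) and *belief exploring-starts* (a fraction of
episodes begins with a random-width belief, the truth sampled from it,
so every entropy bin is trained). Without these, deep-uncertainty states
stay unseen and — because unseen states read as Q = 0 — blind driving
looks maximally safe exactly when it is most dangerous.

## Visual search with EMMA timing

Items are points in degrees of visual angle on a 10°×6° display,
rejection-sampled at ≥2° pairwise separation; the entry fixation is
top-center. Encoding and saccade timing follow the EMMA equations with
K = 0.006 s, k = 0.4/°, t_prep = 0.135 s, t_exec = 0.070 s,
t_sacc = 0.002 s/°. If `T_e < t_prep` the item is encoded covertly;
otherwise the saccade moves fixation to the item, the fraction of
encoding completed during the saccade carries over, and the remainder
re-runs at zero eccentricity.

The item frequency is `f = 1e-5`. This is the one EMMA quantity the
display design pins down: the stimuli are novel trigrams and the items
were separated by ≥2° *so that each requires its own fixation*. At
`f = 1e-5` the covert-encoding radius (`T_e < t_prep`) is ≈1.7°, just
under the separation minimum — so the model, like the participants, must
fixate each item — and per-item cost lands at ~0.25 s, which produces
human-scale trial times. At the commonly quoted `f = 0.01` the covert
radius is ≈4° and the model sweeps the display without moving its eyes.

The search policy is tabular over a coarse state — (fixation cell,
9-bit mask of 3×3 display cells still containing unencoded items) — with
cell-directed actions (encode the nearest unencoded item of the chosen
cell). Action selection is pruned to cells with unencoded items: acting
elsewhere is provably wasted time, and unpruned it creates absorbing
re-encode loops in rarely visited states. Completion pays +10 for target
detection and (by default) the same for exhausting a foil display;
training runs 20 000 / 6 000 episodes with α = 0.3 and τ annealed
2.0 → 0.1 (search rewards are small and nearly deterministic, so the
aggressive step size is safe and coverage matters more).

## Supervisory attention allocation

The supervisory POMDP observes `(bin(max q_drive), bin(max q_search),
focus)` and chooses *drive* or *search*:

* drive: one observed driving cycle (predict + correct);
* search: one EMMA encode, with driving simulated blind underneath in
  dt-sub-steps — prediction-only belief updates, the driving policy still
  steering on the propagated belief;
* a focus change first costs the 34° road↔display saccade, 0.273 s by
  the saccade law, during which neither task progresses and the wheel is
  held. Display fixation persists across road glances (visual short-term
  memory; the return saccade's travel *is* the switch cost).

Max-Q observations are binned by *quantiles* of a warm-up sample
(sticky-random attention with mixed switch rates, so the sample spans
crisp safety through deep blindness). Equal-width bins over the raw range
fail here: the q_drive range is dominated by rare catastrophic values and
the operationally relevant gradient — its slow decline as blind time
accumulates — would disappear into one bin.

Training episodes are continuing 30 s *sessions*: when a search task
completes, a fresh screen replaces it immediately and driving carries on,
as in the experimental procedure. This removes the end-of-trial artifact
in which a trial-final glance is costless. Because the task is
continuing, the supervisor learns with **differential (average-reward)
SARSA**: the update target uses `r − ρ·Δt` with the reward rate ρ
learned alongside (R-learning), durations in driving-cycle units
(semi-Markov steps: an encode may span 0.03–0.8 s). Discounted SARSA at
γ = 0.95 per 0.25 s cycle compounds to ≈19%/s and makes any
glance-splitting rate-suboptimal; differential SARSA optimizes exactly
the joint reward rate. Step sizes are count-adaptive
(`α_eff = max(α, 1/(1+n))`, α = 0.1 floor 0.05 supervisory), so the
first sample of a rarely tried action jumps to its bootstrapped target
instead of creeping up from zero — in continuing tasks with large state
values, constant-α SARSA systematically underestimates rare actions.

Evaluation selects actions by softmax at the *final training
temperature* (0.2): SARSA's values describe the softmax policy at that
temperature, and evaluating colder executes a policy the values never
supported (we measured large behavioral regressions doing so). The
residual stochasticity also plays the role of human trial-to-trial
variability.

SARSA on this deliberately coarse observation is restart-sensitive, so
the supervisory phase trains 3 independent restarts (5 000 full / 1 500
fast sessions each) and keeps the table with the best joint-reward rate
on 24 held-out training-distribution trials — selection on the agent's
own objective, not on any evaluation target.

## The experiment harness

A "participant" is an independent evaluation seed over the shared
condition-trained policies; each runs one continuous session of 24
trials (12 target, 12 foil, shuffled), the car and belief carrying over
between trials. Metrics per trial: trial time; SD of the lateral offset
sampled every driving sub-step; lane deviations counted once at
excursion onset (|x| > 0.85 m); in-car glances defined from the start of
the switch toward the display to the start of the switch back, so
glance durations partition the timeline exactly. Aggregation is
two-stage (participant means, then across participants with SE at
n = participants). Fit indices per metric across condition cells: mean
absolute error, error relative to the human mean, error in human-SD
units, and OLS R² of the human cell means regressed on the model's;
trial types can be pooled or kept separate.

The repository ships a synthetic per-participant human summary (schema:
participant, speed_kmh, n_items, trial_type, metric, value) built from
the published effect structure with participant noise — a stand-in for
exercising `compute_fit_indices`, not data.

## Problem sizes

The default test and reproduction runs use the fast profile (driving
4 000 episodes, search 6 000, supervisory 3 × 1 500 sessions per
condition) and 3 participants × 24 trials × 4 conditions = 288 evaluation
trials; one condition trains in ~3 minutes on one CPU. The full profile
multiplies training by roughly 3–5×.

## What the simulations show — and what they do not

With these settings the simulator reproduces, at 95% bootstrap
confidence on the trial batches: longer trials and longer in-car glances
with 9 vs 6 items; larger lateral-offset SD at 120 vs 60 km/h; longer
foil than target trials; mean in-car glance durations inside the 0.5–1.5 s
band drivers adapt within; and a trained supervisor that outperforms the
always-drive baseline in every condition.

Two known limitations, deliberately left visible rather than tuned away:

* The learned supervisor tends toward *few, efficient glances* —
  typically one to two per task. The items manipulation therefore
  lengthens glances far more reliably than it multiplies them: whether a
  given restart discovers multi-glance interleaving in a given condition
  is seed-dependent, so the glance-count effect of display size can be
  flat or even inverted. On-policy SARSA over the coarse
  (max q_d, max q_s, focus) observation has a robust single-glance
  attractor; hand-crafted threshold policies in the same observation
  space interleave more and score better, so this is a limitation of the
  learner, not of the representation.
* Against the strict-alternation baseline the trained supervisor wins
  clearly at 120 km/h; at 60 km/h alternation is genuinely strong on
  *per-trial* reward (blind-driving risk is low, and alternation buys
  safety with time, which per-trial undiscounted reward does not price),
  and the trained policy loses that comparison. On reward per unit
  time — the quantity the differential learner optimizes — the trained
  policy fares better, but not uniformly across conditions and seeds.

Participant variability here comes only from policy and environment
stochasticity, so the model under-disperses relative to real
participants, and no manual-response (lever-pull) time is modelled, so
absolute trial times sit below human values.
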