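# Methods

## Scope and model structure

`edtrust` simulates one emergency-room shift as a discrete-event system with
four agent kinds: doctors (examine patients, estimate task difficulty, issue
requests), nurses (claim and execute tasks), trainer nurses (mentor, never
execute), and patients (occupy beds, each needing one IV-catheter insertion).
Space is abstracted to a logical topology: beds, a staff waiting room, and a
fixed travel time per leg between them.  Walking, rendering, and room geometry
are presentation, not mechanics, and are deliberately not modeled; `travel_time_s = 0`
removes movement effects entirely.

The event queue is a binary heap keyed by `(time, insertion sequence)`, which
makes every run a deterministic function of `(config, seed)`.  Each agent
draws from its own RNG substream derived from the master seed and the agent's
id, so adding a nurse mid-shift (replacement scenario) never perturbs the
draws of existing agents — the common-random-numbers property that paired
cross-scenario comparisons rely on.

## Task difficulty and durations

Task difficulty is an integer level 1–5.  The gold-standard duration map is
linear, `g(level) = 70 − 10·level` seconds, the minimal strictly decreasing
map through the two anchor points `g(3) = 40` and `g(5) = 20`; any strictly
decreasing table can be substituted in the configuration.  Harder tasks being
*faster* encodes urgency: a difficult task is one that must be done quickly.

True levels are sampled uniformly on {1,…,5} by default (no empirical
distribution is available for the single modeled task type); the distribution
is configurable.  Execution time is `g(true_level) · speed_factor · exp(σ·Z)`
with `Z` standard normal: multiplicative lognormal noise with median 1, so the
speed factor is the median slowdown/speedup.  Defaults: high performers
`s = 0.9, σ = 0.10`; low performers `s = 1.5, σ = 0.25` ("slower and more
variable").  Setting `noise_enabled = false` gives the deterministic mode used
by the oracle tests.

Doctor bias is a fixed level offset (default 2, clamped to 1–5).  A fixed
offset and a jump-to-extreme mapping are indistinguishable on the single
anchored example (3 → 5); the offset is the weaker assumption and is
configurable 1–4.

## The trust policy

The trust update is exponential smoothing toward the binary outcome,
`w ← w + α(outcome − w)`, per requested level, with optimistic initialization
`w₀ = 0.8`, threshold `θ = 0.5`, and a warm-up of `min_attempts = 3` before a
level can be judged.  This is a deliberately simple stand-in with the
qualitative mechanics the scenario design needs: feedback-driven weights and
threshold-triggered self-assessment.

The learning rate defaults to `α = 0.1`.  The calibration target is
*separation*: a provider with the high performer's ~85 % success rate (implied
by `s = 0.9, σ = 0.10`) must almost never dip below θ within a shift
(~140 attempts per level), while a 0 %-success provider must be detected
within a handful of attempts.  At `α = 0.1` a dip requires roughly five
consecutive failures from equilibrium (per-shift misclassification probability
of a high performer in the low percents), while an always-failing nurse drops
below θ after five attempts at a level.  Larger α values (0.2 and up) make
reliable providers self-classify unreliable in a majority of 8-hour shifts,
which inverts the mechanism's purpose.

Self-assessment is per level, recomputed after every outcome, and idempotent.
When any sufficiently attempted level falls strictly below θ the nurse becomes
unreliable and her acceptable range becomes the *capability ladder*: the
longest contiguous run of levels from 1 upward that are all still acceptable
(untested levels count as acceptable), bounded by the configured baseline cap
(default level 2).  Failing the easiest tasks therefore disqualifies
everything above them, and a nurse who fails everywhere ends with an empty
range and idles in the waiting room — the intended terminal state for a
performer whose every attempt misses its deadline.  In the training scenario
no cap is applied: the mentored trainee keeps working at all levels, which is
what the mentoring mechanism needs.

Request claims are exclusive: when a nurse claims a broadcast request it
leaves every other nurse's store, so duplicate execution cannot occur (the
arrival re-check remains as a guard).  Simultaneously idle nurses claim in
ascending id order — an arbitrary but deterministic tie-break chosen for
replayability.

## Scenarios

Scenario hooks fire at most once per nurse, at her first transition to
unreliable, and only under the CA policy (FIFO has no self-assessment, hence
the configuration validator rejects FIFO outside the baseline scenario):

* **baseline** — restriction only, no roster change;
* **replacement** — one additional high performer spawns in the waiting room
  with a store seeded by all currently pending requests; she participates
  until shift end;
* **training** — a trainer spawns and follows the trainee; each mentored
  completion lowers the trainee's speed factor by a fixed decrement, floored
  at the high-performing default.  When the factor reaches the completion
  threshold the trainer leaves and the nurse resumes full responsibilities
  (her restriction, if any, is lifted).

The training decrement defaults to 0.002 per mentored completion: from 1.5 to
the 0.9 floor takes 300 completions, roughly the trainee's task count in an
8-hour shift, so skill improves *gradually across the whole shift* — the
within-shift learning-curve regime appropriate for a manual skill like
IV-catheter insertion.  Tasks whose improvement is nearly immediate can be
modeled by raising the decrement (0.1 reaches the floor in six tasks).

## Metrics

All metrics are computed by a single pure function of the ordered event
stream; the engine feeds it its in-memory records and the `replay` command
feeds it records parsed from the written CSV.  Floats are serialized with
`repr`, which round-trips exactly, so replayed metrics are bit-identical.

Definitions and edge rules:

* *Patients served* counts completed tasks (the single task per patient);
  completion, not the success label, is the criterion — a late task still
  treats the patient.
* *Time damage* compares the actual duration with the **doctor-requested**
  duration, not the true gold standard, consistent with the success label;
  both reflect the requester's judgment.  Duplicate-aborted executions (which
  cannot occur under exclusive claims) would charge zero.
* *Total delay* measures issue-to-claim waiting.  Travel to the bed counts as
  attended: the nurse is committed from the claim onward.  This is a
  borderline reading of "no active nursing intervention" and is the
  documented choice; unclaimed requests accrue until shift end.
* *Doctor evaluation accuracy* is the fraction of issued requests whose
  requested level equals the true level; per-doctor delay totals complete the
  per-doctor view.

## Experiments

The default plan is the four-arm design — baseline-ca, baseline-fifo,
replacement-ca, training-ca — with 60 replicates per arm and seeds
`base_seed + replicate` shared across arms.  Whether the original design
paired seeds across arms is unknowable from the outside; pairing costs nothing
and lowers comparison variance, so it is the default here.

The comparison layer reports Welch's t, the Mann-Whitney rank-sum test,
Cohen's d, and Shapiro-Wilk normality checks, plus a one-way ANOVA /
Kruskal-Wallis omnibus across arms; zero-variance degenerate inputs are
flagged rather than crashed on.  No multiple-testing correction is applied by
default (the tool is exploratory); Holm adjustment is available.

## Verification strategy and problem sizes

* Unit oracles: all closed-form values (duration arithmetic, trust
  trajectories `wₙ = 1 − (1 − w₀)(1 − α)ⁿ`, training step counts) are checked
  against iterated execution; FIFO order against brute-force sorting.
* A from-scratch 1-second time-stepping simulator (`tests/oracles.py`)
  reproduces the event-queue engine's served counts, completion times, damage
  and delay on small noise-free instances (1 doctor, 3 beds, 2 nurses,
  600 s).  It shares only the agent primitives and seed derivation, not the
  scheduling control flow.
* Conservation (per-entity sums equal totals; spawned = served + in beds) and
  bit-exact replay are asserted on full-scale runs of every arm.
* The qualitative policy ordering (FIFO ≥ CA in throughput and damage,
  replacement ≤ baseline in delay, strictly falling trainee durations across
  shift thirds) is checked on 30 paired seeds at the default configuration —
  a desk-scale batch of 120 shifts chosen to keep the whole suite fast while
  leaving the directional comparisons far from their noise floor.

## What the defaults do and do not represent

The default configuration is a deliberately small, controlled ER: one task
type, binary nurse quality, fixed evaluation styles, saturated demand, and no
fatigue, shift transitions, triage prioritization, multi-tasking, or
inter-nurse delegation.  Passing tests demonstrate the mechanics and their
internal consistency under these stylized conditions; they do not calibrate
the simulator against any real department's throughput or harm rates.
Absolute metric values scale directly with the duration map, noise scales,
and shift length, and should be read comparatively (arm vs arm), not as
clinical predictions.

## Known limitations

* The trust update is a documented stand-in, not a reimplementation of the
  published CA update equations, which are outside the modeled scope.
* A request ignored by every nurse simply stays pending; there is no
  re-broadcast or escalation.
* Self-assessment is per level; a global-score variant would trigger earlier
  but restrict more bluntly.
* High performers can (rarely) self-assess unreliable after an unlucky streak;
  this is inherent to threshold self-assessment under noise and is left in as
  emergent behavior — scenario hooks are per nurse, so the roster response is
  well defined.
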