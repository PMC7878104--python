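# Methods

This note documents the models, conventions and numerical choices behind
`steptrain`, and what the synthetic-data checks do and do not establish.

## Stimulus assessment and the cognitive map

A participant's inventory is a set of short thought items, each labelled
with valence ∈ {positive, negative, neutral} and treatment orientation ∈
{approach, avoidance, neutral}.  The similarity-rating task presents every
unordered pair exactly once in a seeded random order (`pair_schedule`).

Similarities on a bounded scale [s_min, s_max] are converted to
dissimilarities by linear reversal, d_ij = s_max − s_ij.  This is the
simplest monotone reversal; since the embedding is nonmetric (rank-based),
any monotone reversal yields the same solution, so nothing of substance
hinges on the choice.  Scale bounds default to (1, 9) and are a parameter.

The 2D embedding is nonmetric MDS minimizing Kruskal stress-1 by SMACOF
majorization, implemented in `stimuli.py`:

- initialization: classical (Torgerson) scaling of the dissimilarities,
  plus `n_init − 1` seeded random restarts (default 4 starts total); the
  lowest-stress solution is kept, ties going to the earlier start, so
  output is a pure function of the input and seed;
- each iteration fits disparities by isotonic regression of the current
  distances on the dissimilarity ranks (stable sort; ties keep input
  order), rescales them to the distances' sum of squares, and applies the
  Guttman transform;
- convergence: relative stress decrease < `tol` (default 1e-6) or
  `max_iter` (default 300).  The per-iteration stress history is exposed
  on the returned map and is non-increasing; this is asserted in tests on
  every input exercised.
- degenerate inputs: an all-zero dissimilarity matrix yields a coincident
  configuration with stress defined as 0 (the stress-1 denominator is
  zero there).

Nonmetric rather than metric MDS because elicited similarity ratings are
ordinal.  A hand-rolled SMACOF (with sklearn's isotonic regression as a
subroutine) is used instead of an off-the-shelf fit because the contracts
here require the stress trajectory and deterministic restart control;
sklearn's SMACOF serves as an independent cross-check in the test suite,
where this implementation must reach comparable or better stress-1.

Classification into probe targets uses the elicited labels only: targets
are approach- or neutral-oriented items with positive or neutral valence.
The cognitive map is attached to the partition as diagnostic provenance
but never drives classification — no published rule maps coordinates to
categories, and inventing a coordinate threshold would fabricate method.

## Dot-probe engine

Protocol constants (all configurable): 1000 ms fixation, 2500 ms stimulus
exposure (fixed, though delivery in the field is only approximately
constant), 50 trials/block, 4 blocks/session, 80% tutorial accuracy gate
(inclusive: exactly 80% passes), 3 sessions/day target over 28 days = 84
sessions.  Response timeout defaults to 5000 ms after probe onset; a
timeout is recorded as `response_side = "none"` and counted incorrect.
Inter-trial interval defaults to 0 ms.

Session plans allocate the four pairing types 13/13/12/12 within each
50-trial block (50 is not divisible by 4); which types receive 13 rotates
across blocks from a seeded offset, so a full session is exactly balanced
at 50 trials per type.  Probe placement: the positive member on
positive-neutral and positive-negative trials (training toward positive,
not merely non-negative), the neutral member on negative-neutral trials,
and a uniformly random side on neutral-neutral trials.  The probed member
of any pair is always a probe target, so the probe never sits on a
negative or avoidance-oriented stimulus.  Left/right placement of the
probed stimulus is counterbalanced within block to at most one trial off
50/50.  Plan generation requires at least one positive probe target, one
negative distractor, one neutral probe target and two distinct neutral
stimuli (a neutral-neutral pair needs two different items) — slightly
stronger than "one of each valence", which cannot actually fill the
design.

Feedback (the audible alert in the delivered app) is modeled as a boolean
event emitted exactly on incorrect trials; whether the field
implementation also signaled correct trials is ambiguous, and error-only
is the conservative reading.  A responder exception mid-session produces
a partial log flagged incomplete; session completeness is all-or-nothing
at block granularity, and only complete 4-block sessions count toward the
84-session program target.

## RT pipeline

Three contractive stages, in this order: (1) keep correct responses only;
(2) one-pass trim at mean ± 1.5 SD, where the reference mean and SD are
computed per participant within assessment period, pooled across pairing
types — the most literal reading of trimming around "a participant's mean
response time"; no iterative re-trimming; groups with fewer than 2
observations are kept untrimmed with a warning and zero-variance groups
are never trimmed; (3) participant-level mean RT per pairing type and
period, then cohort mean and SD over participant means so every
participant contributes equally (between-person SDs of ~600–700 ms, in
line with the design this emulates).  Whether the published trim was
applied within pairing type or per period is not stated; per-period
pooled across types is this package's fixed choice.

Paired comparisons are two-sided paired t-tests (df = n − 1) on the
participant means, computed by `scipy.stats.ttest_rel` and checked in the
test suite against the textbook formula to 1e-10.  Participants missing a
period are excluded pairwise and logged.  Accuracy tables use untrimmed
observations, including timeouts, as correct/total per cell.

## Effect-size conventions

- Paired Cohen d = |t|/√n.  This convention — not the
  mean-difference/SD-of-differences form, which is offered as
  `cohen_d_from_diffs` — is the one that reproduces the reported values
  (t = 4.16, n = 12 → 1.2; 2.71 → 0.78; 3.48 → 1.0); for a paired t the
  two conventions coincide in magnitude.
- φ = √(χ²/n) with n = participants.  The adherence change test is a
  Pearson chi-square (no continuity correction) on the paired pre × post
  2×2 table; an empty margin yields χ² = 0.  Note that a published paired
  χ² generally cannot be re-derived from the printed margins alone, since
  the margins do not determine the off-diagonal (changer) cells; the
  report therefore exposes the full table.
- Percent reduction = 100·(pre − post)/pre, reported to integer percent.
- Two-sided p-values throughout, α = .05, no multiple-testing correction.

Instrument scoring is exact to the printed conventions: PHQ-9 bands
minimal ≤4 / mild 5–9 / moderate 10–14 / moderately-severe 15–19 / severe
≥20 with screening cutoff ≥10; PCL-C total 17–85 with screen at ≥30;
anxiety subset elevated at ≥6; VAS adherence bins 1–3 (≤75% of doses) =
low, bin 4 = moderate/high.  Malformed item vectors (wrong length, range
or missing values) always raise; nothing is imputed.  These are screening
scores, not diagnoses.

## Synthetic cohort generator

The generator's defaults are the study conditions it emulates:

| parameter | default | anchor |
|---|---|---|
| n_participants | 12 | completer sample |
| baseline mean RT | 2550 ms | grand mean of the four pairing-type means |
| between-person SD | 700 ms | reported ~680–770 ms SDs |
| pairing offsets | +3/+29/+11/−67 ms | reported 2553/2579/2561/2483 ms |
| training reduction | mean 330 ms, SD 350 ms | reported 308–369 ms reductions; SD chosen so the implied paired d ≈ 330/350 ≈ 0.94 sits inside the reported 0.78–1.0 |
| within-person noise | ex-Gaussian σ = 150 ms, τ = 300 ms | typical RT skew; no distributional information was published, so these are field-plausible defaults |
| lapse rate | 4% baseline, 2% posttraining | reported 94–98% accuracy |
| PHQ-9 | pre N(13.4, 6.8), change N(4.8, 4.0), truncated/rounded to 0–27 | reported 13.4 → 8.6 at d = 1.2 (change SD = 4.8/1.2) |
| adherence | P(low at pre) = 5/12; P(improve | low) = 0.4; P(worsen | high) = 0 | reported 5/12 → 3/12 low |

Within-person trial RT = person/pairing mean + centered ex-Gaussian noise
(normal σ plus exponential τ minus τ), floored at 50 ms; the right-skewed
tail is what makes symmetric SD trimming bite (~13% trimmed at these
settings).  Errors are independent Bernoulli lapses answering the wrong
side; timeouts occur at a configurable rate (default 0), and simulated
assessment sessions use an effectively unbounded response window because
the probe stays on screen until a response.  PHQ-9 totals are split into
9 items (0–3) by uniform random allocation; only totals are contractually
meaningful.  Generation is a pure function of the seed via spawned
per-participant `SeedSequence`s.

What the generator does **not** emulate: the posttraining between-person
SD shrinkage visible in the emulated design (~375 vs ~693 ms) — an
independent per-person reduction cannot shrink the posttraining SD, and
modeling the baseline-speed × improvement correlation that would produce
it is beyond the published anchors; correlations between instruments;
practice/fatigue within session; counseling effects separately from
training (confounded in a single-arm design).  Passing recovery tests
therefore show the pipeline is consistent and unbiased under a plausible
generative law, not that the published data followed that law.

## Parameter recovery and problem sizes

`parameter_recovery_suite` replicates cohorts, runs the full estimation
path on each (surveys → outcome report; trial logs → filter → trim →
pairing means), and summarizes recovered estimates against generating
values.  Survey-only quantities (PHQ-9 d, percent reduction, phi) use 200
replicates; the trial-level RT pipeline, which simulates 4800 trials per
replicate, uses 40 — enough for a Monte-Carlo SE of ~16 ms on the
recovered mean reduction while keeping the whole suite fast on one core.
At n = 12 the per-replicate spread is large by design (SD of recovered d
≈ 0.4); recovery claims are about the replicate mean.

## Known limitations

- The MDS stress surface is non-convex; with few restarts a suboptimal
  local minimum is possible on pathological inputs (the cross-check test
  bounds this against an independent SMACOF).
- The paired-d convention t/√n is applied to reported t magnitudes
  wherever effect sizes are reproduced; sign information is dropped.
- The adherence chi-square on a 2×2 paired table treats pre and post as
  a contingency classification, matching the emulated analysis; McNemar's
  test would be the textbook choice for paired categories and is easy to
  add downstream from the exposed table.
- One emulated report prints two different t statistics for the same
  symptom change (3.71 in a table, 4.16 in text); only 4.16 is consistent
  with d = 1.2, and the scoring here follows the consistent value while
  the outcome report exposes the full table for auditing.
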