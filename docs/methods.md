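# Methods

This note records the models and procedures engagelab implements, the
defaults and why, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model

A *session* is one recorded group conversation (~30 minutes). Its raw
artifacts are a pitch tier and an intensity tier (time-stamped Hz / dB
samples exported from acoustic analysis), a diarization log of labeled
intervals, and an event-coding sheet. Speaker markers map to groups:
`H` → host, `C` → control (a younger unimpaired adult), `F*`/`M*` →
older-adult participants, `N`/`SO` (noise, significant over-speak) →
excluded everywhere. An *event* is a self-contained interaction segment
(topic raised → last response); it carries eight binary behavior codes
(social, humor, game, cue, affirm, disclose, correct, nonverbal), the
coded number of people speaking, a host one-hot (all zeros = Host 4)
and one engagement score per rater on a 1–5 Likert scale. Times are
seconds everywhere; no frame or sample units.

## Turn structure

Turns are maximal contiguous spans of one speaker's speech. After
dropping `N`/`SO`, globally time-ordered intervals of the same speaker
are merged when the gap between them is at most `merge_gap`
(default 0 s — no bridging; an intervening other speaker always breaks
adjacency). A merged turn remembers its source spans: bridged gaps
belong to the turn's extent but never to speech time, so per-speaker
speech time is exactly conserved by merging and bridged gaps count as
silence in time budgets. Overlapping same-speaker intervals are treated
as a diarization defect and rejected.

An event owns a turn when their overlap exceeds half the turn's extent
(strictly; a turn split exactly 50/50 belongs to neither event). This
rule is a package choice — partial-overlap assignment has no canonical
definition — and is frozen and tested, including the boundary case. The
coded "number speaking" column remains authoritative for modelling;
`distinct_speakers` is a diagnostic cross-check only.

## Prosody normalization and turn features

Pitch and intensity are dominated by anatomy and recording setup, so
each sample is z-scored per speaker per session: `(v − μ_s)/σ_s` with
μ, σ computed over all of that speaker's in-turn samples in the session
and σ the sample (n−1) standard deviation. `ddof=0` is available as a
sensitivity switch. Speakers with fewer than two samples, or zero
spread, cannot be normalized: their samples become missing (with a
warning for zero spread), never silently passed through. Samples
outside every turn are left raw and flagged. Normalization is performed
over in-turn samples only — whether the upstream study normalized over
all audio or in-turn audio is not determinable from its description,
and in-turn is the variant consistent with excluding noise spans.

A turn's six features are the mean, max and min of normalized pitch and
intensity over samples with time in the closed interval
[start, end] (closed endpoints: an arbitrary but fixed and tested
convention). Pitch exists only for voiced frames, so a turn can have
missing pitch features while intensity features exist; missing is a
value state, not an error, and missing sides drop out of proximity
pairwise per feature.

## Entrainment (proximity)

Per event, for each feature, proximity is the mean absolute difference
across sequential turn pairs. Two readings of "sequential pair" are
implemented: `cross-speaker` (default) keeps only adjacent pairs of
different speakers, because a same-speaker adjacent pair measures
self-consistency rather than interpersonal entrainment; `all` keeps
every adjacent pair for sensitivity analysis. "One number per event" is
read as one number per feature per event, since six proximity
predictors enter the acoustic regression. Events with fewer than two
distinct speakers are excluded (an expected data condition reported in
filter counts, not an error). Proximity is invariant to adding a
constant to every turn's feature and to a global sign flip, zero iff
all contributing pairs are equal, and weakly monotone when one turn
moves away from its neighbors — all property-tested.

## Time budgets

Per window: group speech times (turn spans clipped to the window),
participant fraction, and silence fraction `1 − covered/duration`.
The participant-fraction denominator is total speech time by default
(`window` is available as a switch); with no speech it is missing
rather than zero. Silence is "not covered by a kept speaker's speech
span", so noise/over-speak time counts as silence — consistent with
those spans being excluded from analysis. Group times sum exactly to
speech time, silence + covered = 1 exactly, and all features are
invariant under time translation. Event-level models use per-event
windows; session summaries use the whole session span.

## Statistics

All fits are ordinary least squares with an intercept via a QR-based
solver; p values come from the t distribution with n − (k+1) df, the
model F statistic compares against the intercept-only model, and
rank-deficient designs are rejected naming the collinear columns.
Reports pair each predictor's single-predictor fit with its joint-fit
row, mirroring how individual and total models are compared in
practice. Events are pooled across sessions and treated as independent
— no mixed-effects structure — which matches the modelling approach the
pipeline reproduces and is a known limitation (within-session
correlation would make reported SEs anti-conservative on real data).
P values are raw; the report footnote says so.

Host comparisons: groups are optionally balanced by seeded sampling
without replacement down to the smallest host's event count (the seed
is recorded in the report), then one-way ANOVA with
η² = SS_between/SS_total and Tukey HSD at α = 0.05. Inter-rater
agreement is percent exact, percent exactly-one-point-apart, and their
sum ("approximate agreement"); the identity approx = exact + within-one
holds by construction.

## Synthetic generator

Defaults describe a study-scale scenario: 30 sessions split 12/9/7/2
across four hosts, 2–9 participants per session, a control present
with probability 0.93, a log-normal event count per session (mean ≈ 61,
clipped to [6, 209]) and a ~30-minute target length — a busy session
packs its events into the same half hour a sparse one spreads few over,
so turn and gap durations scale with the per-event time budget.
Turn schedule: alternating-speaker renewal process (log-normal turn
lengths, exponential gaps; floor-holding weights 0.35 host, 0.08
control, rest shared by participants); occasional `N`/`SO` spans
exercise the exclusion paths. Event windows tile the schedule so every
turn belongs to exactly one event, and the generated "number speaking"
is computed with the package's own event–turn assignment, making sheets
self-consistent by construction.

Engagement: `score = clip(round(Xβ + ε), 1, 5)` with X the true
per-event predictor vector (behaviors, host one-hot, number, time
features in seconds/fractions), ε ~ N(0, 0.85), and planted β defaulting
to coefficients of realistic magnitude for this predictor set (baseline
1.13; behavior effects 0.1–0.35; host contrasts up to 0.43; 0.24 per
additional speaker; per-second time effects of order 10⁻³). The second
rater is an independent noise draw around the same linear predictor.
The noise sd 0.85 was chosen so the combined model explains a moderate
share of variance at Likert scale, matching what engagement regressions
of this kind typically achieve.

Entrainment is planted in standardized units: each event starts a
fresh N(0, 1) draw per signal and within an event each turn's level is
`(1−δ)·own + δ·previous`. At δ = 1 values collapse to the event draw —
the reset at event boundaries is essential, because chained copying
across a whole session would make per-speaker variance degenerate under
z-normalization. Tier samples are laid down at `baseline_s + sd_s ·
(level + jitter)` every 0.25 s, so per-speaker z-scoring approximately
recovers the planted levels. At δ = 0 the mean cross-speaker proximity
has the closed form E|X − Y| = 2/√π ≈ 1.128.

What the generator does **not** emulate: real voiced/unvoiced pitch
gaps (samples cover whole turns), octave errors, within-session
correlation of engagement beyond the planted predictors, behavior codes
correlated with each other or with the schedule, rater-specific bias or
drift, and overlapping speech. Passing recovery/dial tests therefore
validates the pipeline's arithmetic and statistical calibration under a
correctly specified model, not robustness to those real-data features.

## Recovery and dial experiments

`recovery_experiment` runs the full pipeline per replicate — serialize
the diarization log and event sheet, re-read them through the package's
parsers, rebuild turns, re-extract features, fit — and reports bias,
RMSE and ±2 SE coverage per coefficient. The contract is stated on the
latent continuous engagement response (the correctly specified OLS
model, stored in the planted truth); the 1–5 discretization attenuates
coefficients, and fitting the Likert response is available as the
`likert` diagnostic mode. Acoustic tiers are skipped in recovery
because the combined predictor set excludes acoustic features; the
exercised path is exactly the one that model uses. Note that empirical
coverage estimated from R replicates carries binomial Monte-Carlo
uncertainty with sd ≈ √(0.95·0.05/R) (≈ 1.5% at R = 200), which bounds
how tightly any per-coefficient coverage band can be interpreted.

The entrainment dial uses a denser configuration (4 sessions, 3–4
participants, ~90 events/session, low turn-length variance) so each
speaker contributes many turns per session; per-session normalization
with few effective draws per speaker otherwise inflates measured
proximity by several percent (estimated 1/σ̂ bias plus
duration-weighting mismatch), which is a finite-sample measurement
property, not an error.

## Problem sizes

The test suite and acceptance script size their simulations as follows:
module tests use 2–4 session mini-studies (hundreds of events);
the recovery check uses study-scale replicates (~1 800–2 300 events
each); the dial uses four dense sessions (~300+ multi-speaker events
per δ); identity checks use 50 random turn configurations against a
1 ms occupancy grid. These sizes give Monte-Carlo error small enough
for the stated tolerances while keeping a full run in minutes on one
CPU.

## Known limitations

Praat file support covers the text dialects (short and long) of
PitchTier, IntensityTier and TextGrid interval tiers — not binary Praat
files or point/text tiers. Diarization overlap between different
speakers is tolerated in normalization (earliest turn wins,
deterministically) but is not modelled. Ordinal-response models,
multiple-testing correction and mixed-effects structure are out of
scope by design; the OLS-on-Likert convention is inherited from the
analysis style the package reproduces.
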