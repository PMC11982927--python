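# engagelab

Analytics for social engagement in diarized multiparty conversation
sessions — built for researchers studying group interventions for older
adults with Alzheimer's disease and related dementias (ADRD), where
virtual group sessions are recorded, manually diarized, and coded into
discrete interaction *events* that receive 1–5 Likert engagement
ratings.

The package turns three kinds of raw artifact — Praat pitch/intensity
tiers, diarization logs ("who spoke when", with markers `H` host, `C`
younger control, `F1..F9`/`M1..M7` participants, `N` noise and `SO`
over-speak), and event-coding sheets (eight binary behavior codes,
number speaking, host one-hot, engagement scores from two raters) — into
per-event features and the statistical reports used to identify
predictors of engagement.

## What it computes

**Turns and time budgets.** Diarization intervals become speaker turns
(noise/over-speak spans excluded; optional bridging of small
same-speaker gaps, which never counts as speech). Per window the package
measures speech time by group (host/control/participant), the
participant fraction of speech, and the silence fraction
`1 − covered/duration`.

**Prosodic entrainment (proximity).** Each pitch/intensity sample is
z-scored per speaker per session, `z = (v − μ_s)/σ_s` (sample sd). A turn
contributes six features — mean/max/min of normalized pitch and
intensity — and for each event the proximity statistic per feature is

    d = mean over sequential turn pairs of | f(t_{i+1}) − f(t_i) |

restricted by default to pairs of different speakers; smaller `d` means
interlocutors sound more alike. Events with fewer than two distinct
speakers are excluded from this analysis.

**Engagement models.** Engagement scores are regressed by OLS on
predictor families (host one-hot with Host 4 as reference, the eight
behavior codes, number speaking, time features, acoustic proximity, or
all combined), reporting for every predictor both its single-predictor
fit and its row in the joint fit, plus model R², the F statistic against
the constant model and error df. One-way ANOVA of scores by host reports
η² = SS_between/SS_total with seeded down-sampling to the smallest
host's event count and Tukey HSD post hoc comparisons. Inter-rater
agreement is percent exact, percent within one point, and their sum.
All p values are raw (no multiple-testing correction).

**Synthetic studies.** `engagelab.synthetic` generates complete sessions
(tiers, diarization, event sheets) with known structure: an
alternating-speaker renewal schedule, behavior codes as Bernoulli draws,
an engagement score `clip(round(Xβ + ε), 1, 5)` with planted β, and a
tunable entrainment strength δ that pulls each turn's prosody toward the
previous turn's. Planted truth is stored alongside, so coefficient
recovery and the entrainment dial are testable end to end without any
study recordings.

## Worked example

Simulate a 30-session study, extract features, and fit the combined
model (output shown is what the commands print):

```bash
$ engagelab simulate --seed 11 --out data
wrote 30 sessions, 2070 events to data

$ engagelab extract --diarization data/synthetic_00.diarization.tsv \
    --events data/synthetic_00.events.csv \
    --pitch data/synthetic_00.PitchTier \
    --intensity data/synthetic_00.IntensityTier --out s00.features.csv
wrote 12 events to s00.features.csv

$ engagelab fit --features all.features.csv --model general --out general.csv
general model (rater 1): n=2070 total_R2=0.2566 F=41.66 error_df=2052

$ engagelab hosts --features all.features.csv --seed 7 --out hosts.json
hosts [1, 2, 3, 4]: eta2=0.0629 p=0.0001154 (n per host = 81, seed 7)

$ engagelab agree --events data/synthetic_00.events.csv
exact 41.7% + within-one 50.0% = approximate 91.7% (n=12)
```

Reading the numbers: the combined 17-predictor model explains ~26% of
engagement-score variance on this synthetic study (`total_R2`), with
error df = n − 18 as expected for 17 slopes plus an intercept; host
identity alone shows a small-to-moderate effect size (η² ≈ 0.06) after
every host is down-sampled to 81 events; and on session 00's twelve
events the two simulated raters agree exactly 41.7% of the time and
within one point for another 50%. `engagelab plot` renders the
Turn-at-Talk timeline (host red, female participants blue, male
participants green, control black) plus a JSON segment list.

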