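# ethobuzz

Analysis toolkit for the colony-defence behaviour of bumblebees
(*Bombus terrestris*): ethogram event tables, phase-structured behaviour
metrics, within-bee behaviour associations, stimulus-response
normalisation, defensive-buzz bioacoustics, and inter-onset-interval
rhythm (isochrony) analysis — each exercisable on synthetic data with
known ground truth.

## Who this is for

Behavioural ecologists and bioacousticians scoring colony responses to a
disturbance: every bee of a (micro)colony is observed around a stimulus
applied at time 0 s, each bout of a nine-state ethogram (abdominal
pumping, continuous buzzing, fanning, flying/climbing, grooming, leg
raising, patrolling, perching, pulse buzzing) is recorded with start/stop
times and inside/outside-brood location, and — for acoustic trials —
buzz elements are annotated on mono WAV recordings.

## What it computes

**Phase metrics.** The trial is partitioned into named phases (default:
before disturbance BD [−120, 0), acute response AR [0, 60), delayed
response DR [60, 240), recovery R [240, 480) s). Per bee × phase ×
behaviour the package tabulates occurrence, bout counts, durations
(normalised to seconds per minute of phase) and per-location durations;
it reports participation rates, one-sample t-tests on
outside-minus-inside duration differences, Fisher exact tests with
Bonferroni correction for rare behaviours, and phase-effect regressions —
binomial for occurrence, Gamma/log for durations and velocity — as
marginal GEE models with a within-bee exchangeable working correlation,
with backward elimination (QIC) of candidate covariates and all pairwise
phase contrasts as Wald tests.

**Associations.** Conditional co-occurrence P(X|Y) vs P(X) with
chi-square tests on the bee-level 2×2 table, carry-over across phases,
Spearman correlations of time investments, and observed-vs-independent
counts for four-behaviour suites (Venn analysis).

**Stimulus comparison.** Occurrence probabilities per (behaviour,
stimulus, bin, day, colony) are normalised against the
mechanical-disturbance grand mean as `log((mean + ε)/(grand mean + ε))`,
ε = 10⁻⁵, and analysed with an OLS model `log_ratio ~ stimulus × bin`.

**Bioacoustics.** Preprocessing (22 kHz mono, spectral noise subtraction
with a 30 dB reduction depth, 70 Hz Butterworth high-pass); SNR quality
control (segment RMS over the mean RMS of equal-length flanks, keep
SNR ≥ 1.5); six spectro-temporal metrics (duration, spectral entropy,
mean/dominant frequency, second-harmonic frequency, HNR); MFCCs over nine
equal-length windows × 12 mel coefficients (108 values per call); and a
random-forest check of the manual sound-type labels (20/80 train/test
split with an exact binomial CI and a reverse prediction diagnostic).

**Rhythm.** Inter-onset intervals I_n between successive sound elements,
a pooled 95th-percentile IOI threshold, ratios `r = I_n / (I_n + I_{n+1})`
for same-type ("symmetric") adjacent pairs, categorisation against
small-integer rhythms (1:1 at r = 0.5, band 0.44–0.55; 2:1 at 2/3; 1:2 at
1/3; band edges at ±0.25 on the interval-ratio scale), and a two-sample
KS comparison against a per-recording uniform resampling null. An
isochronous pulse sequence puts its ratios at 0.5 and rejects the null.

## Worked example

```python
from ethobuzz import synth, rhythm as rh
from ethobuzz.phase_metrics import summarize, participation_rate, phase_effect_model
import pandas as pd

spec = synth.default_behaviour_spec()                 # 4 colonies x 20 workers + queen
events, roster, truth = synth.gen_behaviour_events(spec, seed=7)
summaries = summarize(events, spec.scheme, roster)

pr = participation_rate(summaries, "patrolling")
print(f"{pr.worker_performed}/{pr.worker_total} workers ({pr.worker_proportion:.0%})")
# -> 76/80 workers (95%)

res = phase_effect_model(summaries, "occurrence", behaviour="grooming")
print(res.contrasts[["phase_a", "phase_b", "estimate", "se", "p"]].round(3))
```

The grooming occurrence model prints, among others, the BD–AR contrast
`estimate 1.810, se 0.381, p < 0.001`: grooming is suppressed in the
acute-response minute relative to baseline (the generator injects exactly
this inhibition), while the DR–R contrast (`estimate 0.051, p = 0.873`)
is null. For rhythm:

```python
onsets = synth.gen_pulse_train_onsets(17, n_onsets=100)   # isochronous trains
ann = pd.DataFrame(dict(recording_id="r1", onset_s=onsets,
                        sound_type="pulse_buzzing"))
ann["offset_s"] = ann["onset_s"] + 0.05
print(rh.analyze_rhythm(ann, "pulse_buzzing", seed=17).summary())
# Rhythm analysis (pulse_buzzing): 88 observed ratio pairs, IOI threshold
# 0.606 s; KS D = 0.352, p = 3.05e-05; on-integer 1:1 fraction = 0.841
```

The KS p below 0.05 flags the sequence as rhythmic, and most ratio pairs
fall in the on-integer 1:1 band — the isochrony signature.

A thin CLI wraps the same functions: `etho phases --part part1`,
`etho validate events.csv`, `etho metrics events.csv roster.csv`,
`etho rhythm annotations.csv --type pulse_buzzing --seed 17`,
`etho synth behaviour --seed 3 --out demo/`.

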