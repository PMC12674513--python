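# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the procedure was genuinely
open.

## Data model and time conventions

A trial observes every bee of a (micro)colony around a disturbance at
time 0 s; pre-disturbance times are negative. Bouts are half-open
intervals `[start_s, stop_s)`, so a phase boundary belongs to the later
phase and every instant maps to exactly one phase. Bouts of one
(bee, behaviour) may not overlap; different behaviours by one bee may
(the scoring is not forced to be mutually exclusive). Bees that could
not be followed are carried on the roster with an `excluded` flag rather
than silently missing, so denominators are always explicit. "fanning" is
parsed and stored but excluded from the default analysis set (too rare
to analyse); passing the full vocabulary re-includes it.

Two phase schemes ship as defaults: the 10-minute whole-colony design
(BD [−120, 0), AR [0, 60), DR [60, 240), R [240, 480) s) and the
3-minute microcolony design (BD [−60, 0), AD1 [0, 60), AD2 [60, 120) s).

## Phase metrics and models

Durations are attributed to phases by clipping bouts at phase
boundaries; clipping conserves total duration to 1e-9 s. Duration
responses are expressed per minute of phase (`duration_s × 60 /
phase_length_s`) because phases differ in length (1–4 min); modelling
raw per-phase totals would confound phase length with the effect of
interest.

Phase-effect models are marginal regressions fitted by GEE
(statsmodels) with an exchangeable working correlation within the
grouping unit (default: the bee), standing in for random-intercept
mixed models: occurrence uses a binomial family, duration and velocity
a Gamma family with log link (duration models use only bees that
performed the behaviour; zero velocities, whose handling is not
uniquely determined, are floored to half the smallest positive value
and the choice is recorded on the result). Candidate fixed effects
(day, caste) are retained by backward elimination on QIC — the GEE
analogue of AIC selection; the phase term is always retained. The fit
uses a documented retry chain (exchangeable → independence working
correlation → plain GLM) when a fit fails to produce finite estimates.
Pairwise phase contrasts are Wald tests on the coefficient vector;
contrasts involving a phase with no occurrences at all (perfect
separation) are flagged inestimable rather than reported. Measured on
null simulations (80 bees, 4 phases, no effect), the contrast type-I
rate sits inside the binomial 95% band around the nominal 0.05.

Location preference per behaviour and phase is the one-sample t-test of
d = outside − inside duration over bees that performed the behaviour;
unknown-location time is excluded, not imputed; constant samples and
n < 2 are flagged untestable instead of producing a p-value. The rare
leg-raising behaviour is compared across phases with two-sided Fisher
exact tests, Bonferroni-adjusted (p × number of pairs, capped at 1).

## Associations

"Performed during the bin" means the bee-level occurrence flag (any
positive duration), not bout counts. Co-occurrence cells compare
P(X|Y) with P(X) via a chi-square test without continuity correction
(toggleable; the uncorrected statistic is the common default) on the
2×2 bee-level table; cells where either behaviour was not performed at
all, or a marginal is degenerate (0 or 1), are excluded or reported
with a zero statistic. No multiple-testing correction is applied across
the matrix. Agreement with an exact (hypergeometric) test on random
tables with n ≤ 25 is ≥ 95% at α = 0.05. Duration correlations are
Spearman on bees with positive durations of both behaviours, requiring
at least three such bees. The suite analysis counts, per individual
trial, which subset of a four-behaviour panel was performed, and
compares with expected counts from the product of marginal frequencies;
expected counts sum exactly to the number of trials.

## Stimulus comparison

Mean occurrence probabilities per (behaviour, stimulus, bin, day,
colony[, test]) are referenced against the mechanical-disturbance grand
mean per (behaviour, bin, colony) as `log((mean + ε)/(grand mean + ε))`
with ε = 1e-5. The log is natural — the base is not uniquely
determined by the formula, and natural log is the statistical-software
default; it is configurable only in the sense that the normalised table
is plain data. Reference-stimulus rows are retained in the model as the
baseline category (they centre near zero by construction). The model is
OLS `log_ratio ~ C(stimulus) * C(bin)`; the per-cell asterisks are
model-implied cell-mean differences to the baseline stimulus at the
same bin. Rank deficiency (empty cells) is reported on the result.

## Bioacoustics

Preprocessing downsamples to 22 kHz mono, subtracts the mean magnitude
spectrum of a captured noise span (default: the first five seconds)
from every STFT frame with a floor 30 dB below the original magnitude
(the maximum reduction depth; this is magnitude-domain spectral
subtraction, not a bit-exact replication of any editor's denoiser), and
applies a zero-phase 4th-order Butterworth high-pass at 70 Hz.

SNR is the RMS of the annotated span divided by the mean RMS of the two
flanking spans of equal duration. RMS (rather than peak envelope) is
used as "amplitude" for robustness to single-sample peaks. Flanks
truncated by the file edge are used as available with a warning; silent
flanks make the ratio undefined and raise. Annotations with SNR ≥ 1.5
are kept (the boundary is kept); the filter is idempotent.

Spectro-temporal features use a 512-point FFT with a Blackman-Harris
window and 75% overlap (segment length shrinks for short spans).
Entropy is normalised spectral entropy of the mean power spectrum
(pure tone → near 0, white noise → near 1; windowing leakage keeps a
pure tone around 0.2 rather than exactly 0). Mean frequency is the
energy-weighted centroid; dominant frequency the mean per-frame peak
frequency; the second-harmonic frequency is the spectral peak nearest
2 × the autocorrelation-estimated fundamental (the plain "second
harmonic" is otherwise under-defined for noisy spectra); HNR is
10·log10(r/(1−r)) of the normalised autocorrelation peak. These are
approximations of the corresponding spectro-analysis conventions,
verified on synthetic signals with known parameters rather than against
any field dataset.

MFCCs: the annotated span only (no padded context) is cut into nine
equal-length windows; each window yields 12 mel-filter log energies
DCT-II-transformed into 12 coefficients, concatenated to a 108-vector
whose length is independent of span duration. Label verification trains
a 500-tree random forest on a stratified 20% train split (the
deliberately small training fraction makes the test-set check
conservative; a conventional 80/20 split is a parameter away), reports
exact binomial 95% CIs on test accuracy, the confusion matrix, and the
reverse prediction accuracy on the training split; optional class
balancing sub-samples to the smallest class.

## Rhythm analysis

IOIs run from the initiation of one sound element to the initiation of
the next. The outlier threshold is the 95th percentile of the IOI
distribution pooled over all recordings (a single value, reported);
IOIs strictly above it are removed, and ratio pairs spanning a removed
IOI are broken rather than spliced — only IOIs adjacent before
filtering are paired. Only "symmetric" pairs (three bounding sounds of
one type) enter. The ratio is r = I_n/(I_n + I_{n+1}); categories use
the ±0.25 interval-ratio rule with exact fractional edges — the
on-integer 1:1 band is [1/2.25, 1.25/2.25] = [0.4444, 0.5556], which
prints as 0.44–0.55; 2:1 spans [1.75/2.75, 2.25/3.25], 1:2 its mirror;
off-integer bands extend a further 0.25 to 1:1.5 / 1.5:1 etc.; band
edges shared between on- and off-integer go to the on-integer band.
Ratios covered by no band are `other`. Complement symmetry holds
exactly: reversing a pair maps 1:2 ↔ 2:1 and preserves 1:1.

The null replaces each recording's IOIs with the same number of draws
uniform on that recording's observed [min, max]; sound types are
carried over and the null passes through the identical thresholding and
pairing rules, so observed and null have the same per-recording
structure. The observed and null ratio distributions are compared with
a two-sample KS test (pooled per sound type by default; per-recording
available). A required explicit seed drives the null draws.

## Synthetic data: what it emulates and what it does not

The behaviour generator draws per-bee per-phase occurrence as Bernoulli
with spec probabilities, bout counts as 1 + Poisson(rate × phase
minutes), bout durations as Gamma (matching the Gamma/log analysis
family), placed uniformly without within-behaviour overlap, and
locations as Bernoulli per behaviour. The default parameterisation
mimics the qualitative whole-colony response pattern (near-universal
post-disturbance abdominal pumping and patrolling, acute-only
continuous buzzing and leg raising, delayed pulse-buzzing/grooming
peak) purely as a demonstration; tests never assert observed field
percentages from synthetic data. The coupled generator draws joint
occurrence from a log-linear model with pairwise interaction terms and
reduces exactly to independence at zero coupling. What is *not*
emulated: within-trial temporal autocorrelation of bouts beyond phase
structure, bee-level heterogeneity in occurrence propensity, overlap
between behaviours' motor constraints, and any spatial structure —
so passing tests demonstrate correctness of the estimators under the
stated sampling model, not robustness to every feature of real
colonies.

The pulse-buzzing onset generator produces isochronous *trains* of
15–25 pulses (default period 0.5 s, Gaussian onset jitter of 5% of the
period) separated by 2–8 s silent gaps, because real recordings contain
pulse series separated by pauses — the structure the pooled
95th-percentile IOI threshold exists to handle. This matters
statistically: for a single unbroken isochronous train the
per-recording uniform null adapts to the train's tight IOI range and
the KS comparison has essentially no power; with the train-plus-gap
structure the gaps widen the null's range, and detection power for a
100-onset recording is effectively 1. The waveform generator stacks
harmonics with geometric rolloff over Gaussian background noise with
10 ms Hann ramps; element RMS level and noise floor jointly set the
expected segment SNR to √(level² + noise²)/noise.

All generators require an explicit seed and are byte-reproducible.

## Problem sizes and numerical choices

The simulation benches in the test suite use 80–200 bees, 50–500
replicates, 100-onset recordings and 10⁴-draw Monte-Carlo oracles —
sizes at which the measured operating characteristics (type-I inside
the binomial 95% band around 0.05, recovery within 2 SE in ≥ 90% of
replicates, isochrony power ≥ 95%) are stable across seeds while the
whole suite runs in well under a minute per bench. Degenerate inputs
are flagged rather than guessed at throughout: zero-variance location
differences, all-zero phases (inestimable contrasts), constant
durations (undefined Spearman), silent spans (undefined features),
degenerate IOI ranges (recording skipped in the null).

## Known limitations

- GEE marginal coefficients are population-averaged; with substantial
  bee-level heterogeneity they are attenuated relative to
  subject-specific mixed-model coefficients. The contrast *tests*
  remain valid (robust covariance), which is what the pipeline reports.
- The spectral features approximate, but do not bit-reproduce, any
  specific acoustic-analysis suite; entropy and HNR conventions differ
  across tools.
- The suite-analysis independence expectation uses realised marginal
  frequencies, so it is a plug-in expectation without uncertainty
  propagation; observed-vs-expected comparisons are descriptive.
- No automatic sound-event detection: annotations are inputs.
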