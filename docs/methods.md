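# Methods

## The estimation problem

Overnight sleep staging is normally done from EEG/EOG/EMG by trained
scorers on 30-second epochs.  This package implements the reduced
problem of *binary* sleep/wake scoring from anterior tibialis (shin)
surface EMG alone.  The physiological premise: wakefulness — even
motionless wakefulness — carries elevated leg-EMG tone and short
high-amplitude bursts (body movements, isometric activity), while sleep
shows low tonic amplitude.  Stages 1–4 and REM are all mapped to SLEEP;
only stage W is WAKE.  Anterior tibialis tone does not reliably drop at
the NREM→REM transition (unlike chin EMG), so no attempt is made to
score REM separately; that is out of scope by design.

## Time-domain estimator

The raw samples are squared and summed per second (`y_k`) and per epoch
(`z_l`).  No filtering or detrending precedes the squaring; an optional
per-epoch DC removal (`remove_dc`) exists because stored recordings can
carry offsets that squaring would misread as tone, but it is off by
default since the method as specified applies none.

Epoch `m` receives the adaptive threshold
`T_m = tsf1 * mean(z[m-tsf2 .. m+tsf2])`.  The printed form of this
window in the source material is typographically inconsistent; the
implementation follows the unambiguous prose description — a symmetric
window of `2*tsf2+1` epochs centred on `m` ("previous 25, current 1,
subsequent 25" in the worked setting `tsf1=4, tsf2=25`).  Boundary
policy (unspecified in the source): the window truncates at the
recording edges and the divisor is the number of epochs actually inside
it, so `T_m` is always an average of observed energies and every epoch
is scored.  Zero-padding would bias edge thresholds low; dropping edge
epochs would leave the first and last 12.5 minutes unscored.

`HEMG_m` counts seconds in epoch `m` with `y_k` strictly above `T_m`
(the defining sign convention, `sgn(0)=0`, makes the comparison strict;
values run 0–30 — the comparison is between per-*second* energies and
the threshold, not raw samples).  The epoch is WAKE iff `HEMG_m`
strictly exceeds the whole-night mean count.  Ties therefore break
toward SLEEP.  The mean makes this an offline algorithm: the full night
is needed before any epoch is scored.

Both `y` and `T` scale with the square of the signal amplitude, so the
classification is exactly invariant to positive rescaling — the reason
no amplitude units or electrode-gain calibration are required.

## Frequency-domain estimator

Per epoch, a one-sided periodogram of the whole 30-s window (plain FFT,
no taper, no detrend; 1/30 Hz resolution) is summed over 10–75 Hz with
55–65 Hz removed.  Below 10 Hz live baseline/movement artefacts, above
75 Hz mostly amplifier noise; 55–65 Hz covers 60 Hz mains hum with
±5 Hz drift margin (configurable, e.g. 45–55 Hz in 50 Hz regions; the
mask can be disabled).  Band edges: 10 and 75 Hz bins are retained,
55 and 65 Hz bins are excluded.  The power scale is chosen so that with
no masking the bin sum equals the epoch's sum of squares (Parseval),
making `tp_m` commensurate with the time-domain epoch energy.  A Hann
taper is available (`window="hann"`) but off by default: the plain
transform is the estimator as specified, and any taper would be an
undocumented extra choice.

The decision threshold is `tsf1 * mean(tp) + tsf2 * std(tp)` with the
sample standard deviation (divisor N−1, configurable via `ddof`).  By
default the statistics come from the recording being scored — the
threshold adapts to each subject's EMG tone; a precomputed (training)
threshold can be passed instead.  Scoring needs at least 2 epochs (std
undefined otherwise) and a sampling rate above 150 Hz (else the
retained band would be clipped).

## Calibration

`tsf` pairs are selected by exhaustive grid search maximizing the mean
Cohen's kappa over training recordings.  Kappa, not accuracy, because a
normal night is ~97% sleep: a constant-SLEEP scorer achieves 97%
accuracy and kappa 0.  (Accuracy and F-measure remain available as
objectives.)  Ties break deterministically toward smaller `tsf1`, then
smaller `tsf2` (less aggressive thresholds).  Default grids:
TDA `tsf1 ∈ {1..10}`, `tsf2 ∈ {5,10,…,50}`; FDA `tsf1 ∈ {0,0.25,…,2}`,
`tsf2 ∈ {0.5,1,…,5}` — bracketing the documented exemplar settings
(4, 25) and (0.5, 3.5) by roughly an order of magnitude each way.
The leave-one-out harness trains each fold on all other recordings and
scores the held-out night; only the factors transfer — the adaptive
thresholds themselves are always recomputed on the scored recording.
Grid points whose objective is undefined on every training item (e.g.
single-class references) are skipped; if that exhausts the grid,
calibration fails loudly.

## Agreement statistics

Positive class is SLEEP: sensitivity = TP/(TP+FN) is the recovered
fraction of sleep epochs, specificity = TN/(FP+TN) the recovered
fraction of wake epochs.  Kappa uses the marginal-product chance
agreement.  The F-measure is the harmonic mean of PPV and sensitivity
(precision/recall).  The benchmark literature for this method describes
F verbally as a sensitivity–specificity harmonic mean but prints values
that match the PPV–sensitivity definition; the printed numbers win, and
the verbal variant is available as `f_variant="sens_spec"`.  Epochs
EXCLUDED in either sequence (unscorable reference epochs) are dropped
pairwise; single-class references yield NaN for the undefined ratios
with a warning, never an exception, so cohort loops survive degenerate
nights.  Sleep-efficiency comparison reports the absolute difference in
percentage points and the relative difference as a percentage of the
*reference* (PSG) efficiency.  Summary rows aggregate per-subject
statistics as mean and sample SD (divisor n−1).

The state-amplitude histogram normalizes absolute amplitudes by the
recording maximum (support exactly [0,1], unit mass per state) and
compares per-epoch mean normalized amplitude between states with the
two-sample Wilcoxon rank-sum test.  Its type-I error is verified by
simulation to sit near the nominal 5%.

## Synthetic data generator

The generator emulates the *signal phenomenology the estimators use*,
not muscle physiology — there is no motor-unit model.  Ground truth is
a two-state Markov chain started from its stationary distribution, with
transition probabilities solved from the target sleep efficiency
(default 97.5%) and mean wake-bout length (default 2 epochs ≈ 1 min).
Stage labels within sleep come from a sticky chain whose stationary
distribution approximates a normal night (S1+S2 ≈ 65%, S3+S4 ≈ 12%,
REM ≈ 23%); they exist for format realism and play no role in the
signal model.

The signal per channel is unit-variance 10–75 Hz Gaussian noise scaled
by a tonic amplitude (`sigma_sleep = 1` asleep, `sigma_wake = 3` awake)
and a movement envelope: wake epochs receive Poisson-placed Hann-shaped
bursts (default 6/min, 0.5–3 s, amplitude ×8), shared across both
channels (movements are bilateral) while the noise itself is only
partially shared (`channel_correlation = 0.5`).  Optional additions: a
pure 60 Hz sinusoid (mains hum), and periodic-leg-movement trains.
The PLM profile models a severe phenotype: movements every 20 s, 4 s
long, amplitude comparable to waking movement bursts, occurring in
sticky trains covering ~60% of sleep (≈ a PLMS index near 100/h) —
parameter ranges follow the standard PLMS scoring definition (0.5–10 s
duration, 5–90 s spacing).  The cohort generator jitters per-subject
amplitudes and burst rates (±20%) and target efficiency (SD 0.8
points); the `osa` profile keeps the normal signal model (apnea does
not alter leg-EMG phenomenology) with a more fragmented hypnogram, and
`plmd` enables the PLM trains with slightly lower target efficiency.
Everything is deterministic given the seed.

What passing synthetic tests do *not* show: real EMG has heavy-tailed,
nonstationary bursts, ECG cross-talk, electrode pops and impedance
drift, none of which are modelled; synthetic recovery (kappa ≈ 0.95+)
is therefore an upper bound, not a forecast of clinical agreement
(≈ 0.6–0.7 in the published validation).

On synthetic cohorts, leg-movement trains degrade wake specificity when
the threshold factors are *fixed* (as when calibration data are
dominated by non-PLM sleepers): PLM energy inflates the adaptive
thresholds and the mean HEMG count, and genuinely-wake epochs fall
below the raised decision lines, while sensitivity stays high.  A pure
within-PLMD recalibration largely compensates on synthetic data — the
degradation is a property of transferred thresholds, which is how the
acceptance suite exercises it (exemplar factors (4,25) and (0.5,3.5)
applied to both profiles).

## Numerical and I/O choices

* Epochs are whole 30-s blocks; a trailing partial epoch is dropped
  with a warning.  Signal/hypnogram length mismatches of one epoch are
  truncated to the common length (a common export off-by-one); larger
  mismatches are errors.
* Frequency-bin band masks use a 1e-6 Hz tolerance so bins that land on
  band edges are classified by intent, not floating-point accident.
* EDF files are written as continuous EDF with 1-s records and 16-bit
  samples; the round-trip error is bounded by the per-channel
  quantization step `(2·max|x|)/65534`.  Amplitudes are used exactly as
  stored — no unit rescaling — because both estimators are
  scale-invariant.
* Problem sizes in the test and acceptance suites: oracle-equivalence
  and invariance checks run at 20 Hz / 200 Hz on nights of up to 20
  epochs (hundreds of random instances); synthetic recovery runs the
  full documented conditions — 6 subjects × 960 epochs at 250 Hz; the
  rank-test calibration uses 2000 null simulations of 24-epoch
  recordings at 20 Hz.

## Known limitations

* Offline only: both decision rules need whole-night statistics.
* No artifact rejection (ECG contamination, electrode pops) and no
  resampling — only integer samples-per-second rates.
* The generator's stage labels are cosmetic; do not use it to evaluate
  stage-level (non-binary) scorers.
* For PLMD-like signals the estimators systematically overestimate
  wake; the package reports this honestly rather than correcting it —
  for such recordings the tool is better used as a leg-movement
  tracker than a sleep-efficiency monitor.
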