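# Methods

## The problem and the data model

The package classifies cumulative physiological stress from heart rate
variability in a rodent chronic-mild-stress design with three groups —
control, short-term stress (SS, two weeks) and long-term stress (LS, four
weeks), 15 animals per group, single-lead telemetry ECG sampled at 1 kHz for
5 min per session, split into two non-overlapping 150-s trials.  Long-term
stress mainly depresses the time-domain HRV measures (longer, less variable
heart periods); short-term stress mainly shifts the sympathovagal balance in
the frequency domain (nLF up, nHF down).  The question the pipeline answers
is which small subset of the 11 standard HRV features best separates the
three states.

Because the underlying recordings are not deposited, the synthetic-data
module is a first-class component: every downstream stage is developed and
tested against data whose generating parameters are known.

## Calibration of the feature generator

Each group is specified by a mean and SD per feature (`GroupSpec`).  Means
and SEMs come from the published post-test group statistics; SDs are
SEM·√15.  Eight features are sampled directly from truncated Gaussians
(mRR, mHR, SDRR, RMSSD, pNN5, lnLF, lnHF, nLF; truncation to physical
ranges by resampling, not clipping, to avoid probability spikes at the
bounds), and three are derived per row so the algebraic identities of real
HRV vectors hold exactly:

    CVRR = 100·SDRR/mRR,   lnLFHF = lnLF − lnHF,   nHF = 100 − nLF.

Cells that were not printed for a group are filled by a declared policy:

- **SS time domain** = the control post-test values.  The study found no
  significant SS–control time-domain differences, so the control level is
  the natural fill.
- **LS frequency domain**: the study reports only LS's within-group
  pre-to-post changes (lnLF −0.84, lnHF −1.02 ln ms²).  Taking the control
  post-test level as the common baseline gives LS lnLF = 0.60 and
  lnHF = 0.20; LS nLF = 59.87 then follows from the logistic identity
  nLF = 100·e^x/(1+e^x) at x = lnLF − lnHF = 0.40.  (The same identity
  reproduces the printed control pair — x = 0.22 → 55.5 vs printed 55.41 —
  which supports the reconstruction.)
- **lnHF means** follow from lnHF = lnLF − ln(LF/HF): control 1.22, SS 0.83.
- **lnHF SEMs** default to the same group's lnLF SEM.  The printed ln(LF/HF)
  SEMs (±0.78/±0.89) are an order of magnitude larger than the printed nLF
  SEMs imply through the logistic delta method and are treated as not
  propagatable; they are carried in the calibration table as metadata only
  (ln(LF/HF) is a derived column and is never sampled from).

Two notes on fidelity.  mHR is the mean of instantaneous rates
(mean of 60000/RR_i): the printed control pair (mRR 166.82 ms,
mHR 362.99 bpm ≠ 60000/166.82 = 359.7) is consistent only with that
definition, reflecting the nonlinear rate–period relationship.  And the
generator draws the eight independent features **independently**: it
reproduces each group's marginal distributions but not the cross-feature
correlation structure of real HRV (SDRR–RMSSD–pNN5, mRR–mHR, lnLF–nLF are
strongly coupled in real tachograms).  Tests that pass on this generator
therefore validate the machinery and the marginal separations, not
correlation-driven effects; in particular, feature rankings on synthetic
data make de-correlated features (RMSSD, lnLF, lnHF) *more* competitive
than they are in real data, where redundancy dilutes their SVM weights.

## Tachogram and ECG synthesis

`generate_rr_tachogram` uses an interval-modulation model,

    RR_i = mean_rr + lf_amp·sin(2π f_LF t_i) + hf_amp·sin(2π f_HF t_i) + ε_i,

with ε_i ~ N(0, noise_sd²) and t_i the cumulative beat time.  Defaults:
mean_rr 160 ms (rat resting range), modulation amplitudes 2 ms, f_LF 0.4 Hz,
f_HF 2.0 Hz (band centres), noise 1 ms, duration 150 s (one trial).  Its
band content is analytically known, which is why it is preferred over an
integral-pulse-frequency-modulation model.  Validity requires
lf_amp + hf_amp + 3·noise_sd < mean_rr so intervals stay positive.

`synthesize_ecg` places one Gaussian R-wave template (FWHM 10 ms,
amplitude 1 mV) per beat on a uniform grid (default 1 kHz) plus optional
white noise.  No P/T waves, baseline wander or ectopy are modelled — the
trace exists to exercise R-peak detection, not morphology analysis.

## Signal chain

The R-peak detector is a Pan–Tompkins-style chain: 2nd-order Butterworth
band-pass 10–50 Hz applied forward-backward (zero phase, hence
shift-equivariant), derivative, squaring, 20-ms moving-window integration,
peak picking on the envelope at 0.2× its 99th percentile with a 50-ms
refractory distance (rat rates up to ~500 bpm never collide with it), then
refinement of each detection to the raw-signal maximum within ±25 ms.
Flat or non-finite input yields an empty series with a warning rather than
an error.  Polarity is taken as given; `invert=True` handles negative-R
leads.  Trials are consecutive non-overlapping 150-s windows; a trailing
remainder is discarded (a 5-min recording yields exactly two trials).  An
optional physiological-range interval filter exists in concept but is off:
the source protocol describes none, and the synthetic data contain no
artefacts.

Measured closure on synthetic ground truth: noise-free detections land
within half a sample of the template centres; at 20 dB SNR sensitivity and
positive predictivity are 1.00 with a 10-ms match tolerance (the test suite
asserts ≥ 0.99).

## Spectral estimation choices

The interval series is cubic-spline interpolated to a uniform 20-Hz grid
(Nyquist 10 Hz, well above the 3.5-Hz HF edge) and analysed with Welch's
method: Hamming window, 512-point segments (25.6 s), 50% overlap, constant
detrend — about ten half-overlapped segments per 150-s trial.  Band powers
are trapezoidal integrals of the density, LF over [0.1, 1.0) and HF over
[1.0, 3.5] (the shared edge counted once, on the HF side).  Zero band power
raises `DegenerateInputError` rather than returning −∞ logs.  A series
shorter than one full segment falls back to a single full-length window
with a warning; pNN5 uses strict |ΔRR| > 5 ms; SDRR uses the n−1
denominator (configurable).

## Ranking and evaluation

All data are min-max scaled to [0, 1] once, before the elimination loop
(matching the declared preprocessing order; a leakage-safe per-fold mode is
available by pre-scaling externally).  The three OVA SVMs are linear-kernel
soft-margin machines (libsvm via scikit-learn), C = 1 by default — the
criterion J_j = max_r (w_j^r)² is defined on primal weights and therefore
only for the linear kernel; nonlinear kernels appear solely as evaluation
classifiers.  One feature is eliminated per iteration; exact ties eliminate
the feature latest in canonical order.  Per-iteration |w|/‖w‖ is recorded
per model, plus the row-wise max, as the weight-colormap diagnostic.
Ranking sensitivity to C is real and worth inspecting with the shipped
diagnostic (re-fit at C ∈ {0.1, 1, 10}): smaller C concentrates weight on
the dominant separators, larger C spreads it.

Evaluation runs repeated stratified 5-fold cross-validation (default 10
repeats with distinct fold seeds derived from one master seed via
`SeedSequence`); the reported dispersion is the SD of per-repeat accuracies.
Multiclass accuracy is the overall fraction correct, the micro average of
the per-class one-vs-rest (TP+TN)/total tallies.  Classifier defaults:
SVM C = 1 for all kernels, polynomial degree 3, RBF bandwidth
1/(D·Var(X)), k-NN k = 5, LDA with its usual SVD solver.  QDA is a
package-local Gaussian discriminant (`RidgeQDA`) whose class covariances
get an additive ridge 10⁻⁶·(tr Σ/D)·I: the 11-feature vector is exactly
collinear by construction (nHF = 100 − nLF, lnLFHF = lnLF − lnHF), so an
unregularised QDA is undefined on any subset containing both members of a
derived pair.  A fold on which a classifier still fails is warned about,
counted, and excluded from that repeat's tally.  The optimal subset is the
rank-prefix with maximal mean accuracy, ties toward fewer features; since
the argmax ranges over all prefixes including the full set, the optimal
subset's mean accuracy never falls below the all-features accuracy on the
same folds.

Fold construction is trial-wise (each row independent).  The generator
labels rows with subject/trial ids so a subject-aware grouping mode can be
built on top, but with i.i.d. synthetic rows grouping changes nothing.

## Problem sizes

Defaults throughout mirror the source design: n = 30 samples per group
(15 subjects × 2 trials), 5 folds, 10 repeats, 10 replicate seeds for
headline numbers; 150-s trials at 1 kHz for signal-level work.  The full
test suite plus the acceptance computation completes in a few minutes on a
single CPU at these sizes.

## Known limitations

- Marginal, not joint, calibration (see above): no cross-feature
  correlations, no within-subject correlation between a rat's two trials,
  no pre-test state.
- The ECG model omits P/T waves, wander, ectopic beats and pathology; the
  detector is validated only against that model and white noise.
- LS frequency-domain calibration cells are reconstructed from within-group
  changes, not printed post-test values.
- No nonlinear HRV measures, VLF band, or Lomb–Scargle spectra; no
  statistical testing on accuracy differences.
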