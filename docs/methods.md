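# Methods

This note documents the models, algorithms and numerical choices behind
`egmscore`, and what the synthetic-data tests do and do not establish about
behaviour on clinical recordings.

## Signal model and band split

A bipolar electrogram from the distal ablation electrode at an
accessory-pathway target is modelled as the superposition of a slow,
large far-field ventricular deflection and a sharp, fast near-field
potential, recorded within a 30–500 Hz hardware band at ~1 kHz sampling.
The two are separated with a Butterworth low-/high-pass pair at the split
frequency (default **100 Hz**, order **4**), applied forward–backward
(`scipy.signal.sosfiltfilt`) so both components are strictly zero-phase and
share the raw time axis. The split frequency and order are configurable
(`RunConfig.split_freq_hz`, `filter_order`); 100 Hz is chosen because
far-field ventricular content lies almost entirely below it while
near-field pathway potentials carry substantial energy above it.

Edge handling: the input is odd-reflection padded before filtering. The pad
length is the larger of three split-frequency periods and the slowest
pole's settling length to 1e-12 (≈121 samples at the defaults); shorter
pads leave edge transients (~5e-4 mV) that break the zero-phase
time-reversal symmetry the test suite asserts at 1e-9 mV. Recordings
shorter than the pad are rejected as insufficient data.

The two Butterworth branches are not exactly power-complementary; the test
suite asserts energy preservation only as a bound (≥ 80% of the in-band
energy), not as an identity.

## Landmarks

* **R peak** — time of maximum |lead I| within the beat window; ties break
  to the earliest sample. Maximum *absolute* value is used throughout
  because bipolar polarity is arbitrary.
* **LF peak** — time of maximum |LF| within the beat window, same tie rule.
* **HF onset** — earliest time the HF amplitude envelope (magnitude of the
  analytic signal, `scipy.signal.hilbert`) exceeds `k×SD` of the noise
  baseline continuously for a sustain interval (defaults `k = 3`,
  **5 ms**). The envelope, not the rectified trace, is thresholded: a
  narrow-band burst at 200 Hz crosses zero every 2.5 ms, so no rectified
  sample run can stay above a threshold for 5 ms. The baseline is the
  earliest 20% of the beat window (`baseline_frac`); if the detected onset
  falls inside the baseline segment, the SD estimate is contaminated and a
  warning is emitted. Flat traces and never-crossing envelopes raise
  detection errors rather than returning a guess.

**Beat selection.** The analysis beat is the last one wholly preceding
energy delivery: the beat whose R peak is the last strictly before the
energy-onset time. Its window is the preceding R–R cycle shifted right by
`beat_shift_ms` (default **100 ms**) and capped at the energy onset. The
shift makes the half-open window contain the beat's own R peak *and* its
pre-R activity (the HF onset typically precedes the R peak by ~125 ms)
while excluding the neighbouring beats' deflections; an onset exactly on an
R peak therefore selects the prior beat.

## Features and the composite score

All integrals are trapezoid integrals of rectified (absolute-value) traces;
bipolar signals integrate to ≈0 unrectified, so only rectified areas carry
amplitude–duration information. Fractional window endpoints are handled by
linear interpolation of the rectified trace, so the value is invariant
under refinement of the rectified trace's grid (asserted against a 10×
oversampled oracle at 1e-9).

Per signal the package computes: HF and LF amplitudes (peak absolute value;
a peak-to-peak mode is available), the three landmark intervals (HF onset →
LF peak, HF onset → R, LF peak → R, in ms), the rectified HF and LF areas
over the beat, a windowed HF area (±25 ms around the HF onset), the HF
ratio (fraction of total rectified HF area falling inside the scoring
window, in [0, 1]), and the **composite score**: the rectified HF area
within ±`window_halfwidth_ms` (default **25 ms**) of the LF peak, in mV·ms.
The scoring window is clipped to the beat window; a window entirely outside
it is an error. Note the windowed-HF-area and HF-ratio definitions are the
package's reading of ambiguous nomenclature in the source material for
those two quantities; they are configurable and do not feed the composite
score.

**Classification.** A signal is called successful iff
`score > threshold` with strict inequality and default threshold **3.1**.
The tie goes to "unsuccessful" deliberately: a false success costs a wasted
lesion, a false failure only an extra mapping step.

## Diagnostics

The ROC is traced over all unique score values as thresholds (descending,
terminated at −∞), with predicted-positive defined by the same strict
`score > t` rule as the classifier. Ties in scores produce diagonal
segments and the trapezoid area equals the tie-adjusted Mann–Whitney
concordance exactly (asserted property). Threshold selection:

* **Youden** — maximize J = TPR − FPR (prevalence-independent);
* **cost–benefit** — maximize TPR − r·FPR for a ratio r > 0 (default
  **1.5**), which weights false positives r-fold and shifts the cut toward
  specificity; r = 1 reduces to Youden and the selected threshold is
  non-decreasing in r.

Ties in either objective resolve to the higher (more specific) threshold.
Operating-point metrics use the closed-form ratios; a zero denominator
yields NaN rather than a silent 0. Quantiles in the per-class feature
summaries use linear interpolation (type 7), which the IQR endpoints depend
on; LF-to-R time is summarized as mean ± SD (it is approximately
symmetric), all other features as median (IQR). An optional clustered
bootstrap (resampling whole patients) provides an AUC confidence interval.

**Difficult ablations** are procedures requiring strictly more than the
cohort-median number of lesions (median taken over patients); all signals
of those patients are pooled and classified at the configured threshold.

## Lasso logistic refinement

The refinement model is an L1-penalized logistic regression of outcome on
the a-priori predictor set: gender, HF-to-R, HF-to-LF and LF-to-R times,
congenital heart disease, pathway side, LF and HF integrals, and the
composite score. Skewed continuous predictors (scores, areas, the HF timing
intervals) are log-transformed; all predictors are standardized.
Two-level categorical predictors are coded 0/1 (the encoding is recorded on
the fit); constant predictors are dropped with a warning.

The penalized likelihood is maximized with `statsmodels`'
`Logit.fit_regularized` (L1, per-parameter penalty weights with **zero
penalty on the intercept**, exact zeros via coefficient trimming). The
penalty strength is chosen by k-fold cross-validation (default **10**
folds) written explicitly: folds are stratified by outcome and grouped by
patient (`StratifiedGroupKFold`), so repeated signals from one patient
never straddle a fold boundary; the out-of-sample deviance (log-loss) is
averaged per penalty value, and the **one-standard-error rule** picks the
strongest penalty within one SE of the best — the glmnet convention, which
favours sparser models over the deviance minimum. Seeded fold shuffling
makes fits bit-reproducible. Very large coefficients trigger a separation
warning (the L1 penalty caps, but does not remove, the divergence). At
penalties strong enough to zero every slope, the fitted intercept equals
the log-odds of the prevalence, as it must with an unpenalized intercept.
Selected probability-scale thresholds are then evaluated with the same
Youden / cost-benefit machinery.

A caveat recorded for reproducibility: cross-validated threshold choices on
the probability scale depend on the exact CV partition; they are reported,
but not treated as reproducible constants.

## Synthetic data

### Waveforms

Each simulated beat places, relative to its R peak at `r_first + k·RR`
(default RR **600 ms**): a LF burst (Gaussian-envelope cosine, 60 Hz,
60 ms, 0.3 mV) peaking 70 ms before the R peak; a HF burst (200 Hz, 70 ms,
0.5 mV) switching on 55 ms before the LF peak; a Gaussian QRS on lead I
(1 mV, 80 ms); and white noise (default SD **0.02 mV**). These intervals
match the typical observed landmark geometry (HF→LF 55 ms, LF→R 70 ms,
HF→R 125 ms). Burst envelopes are truncated at ±duration/2 with
σ = duration/3, so they switch on at ~32% of peak amplitude — the abrupt
take-off characteristic of near-field potentials, and the property that
makes a "window start" ground-truth onset detectable to within the sample
grid; cosine phase puts the true peak exactly at the envelope centre.
Ground-truth landmark times are returned per beat, and everything is
deterministic under the seed.

What the waveform generator does **not** model: fractionated or multi-
component near-field potentials, pacing spikes, baseline wander, T waves,
respiration or motion artefact, beat-to-beat variability. Landmark-recovery
results (median errors ≤ 2 ms for LF/R peaks and ≤ 3 ms for HF onset at
SNR 10 over 200 seeded beats) therefore characterize the detectors under
clean morphology and stationary noise only.

### Feature cohorts

The cohort generator draws per-signal feature records patient by patient:

* **Lesions per patient** follow a fixed distribution with median 2, a ~23%
  tail of difficult procedures (≥3 lesions, up to 15) and mean ≈2.3
  signals per patient; each lesion contributes one signal, and the final
  lesion is the successful one with probability **0.97** (the empirical
  per-patient acute success rate), making ≈41% of signals successful.
* **Features** are drawn from class-conditional log-normal distributions
  whose median and IQR match the published per-class summary of the
  validation cohort (composite score 5.4 (3.7–8.3) successful vs 2.3
  (1.6–3.2) unsuccessful, and correspondingly for amplitudes, areas and
  the two HF timing intervals); LF-to-R time is normal (71 ± 27 /
  70 ± 22 ms). Log-normality is the natural choice for positive,
  right-skewed quantities reported as median (IQR).
* **Clustering**: signals within a patient share a Gaussian random effect
  (SD **0.2**) on the log composite score; the residual SD is shrunk so
  the *marginal* class distributions keep their anchored medians/IQRs.
* **Covariates** (sex 67% male, left-sided pathway 46%, CHD 5%, cryo 6%,
  transseptal approach 67% of left-sided, atrial pacing 6%) are drawn at
  the patient level at the cohort's observed prevalences and are
  independent of outcome.

Two structural simplifications matter when reading results obtained on
this cohort. First, features are **class-conditionally independent**
(beyond the shared patient effect on the score), whereas real features are
computed from the same trace and are strongly correlated; a multivariable
model therefore gains more on synthetic data than it can on real data —
the lasso's in-sample AUC on the synthetic cohort (~0.94) overstates what
the published refinement achieved (~0.81). Second, the two-parameter
log-normal score model calibrated to the published medians/IQRs implies an
AUC of Φ((μ₁−μ₀)/√(σ₁²+σ₀²)) ≈ 0.86, a few points above the published ROC
area (0.80–0.81); the published class summaries and ROC are not jointly
consistent with any such two-parameter model, and this package calibrates
to the class summaries. Sensitivity (~0.82) and specificity (~0.72) of the
3.1 cut on the synthetic cohort equal the model's analytic exceedance
probabilities and sit within a few points of the published operating point
(0.87 / 0.73).

## Configuration and reproducibility

All tunable parameters live in `RunConfig` (YAML/JSON loadable): split
frequency and filter order, scoring half-width, decision threshold, onset
detection constants, beat-window shift, cost-benefit ratio, CV folds,
seed, amplitude mode, an optional score scale factor (default 1; hook for
matching a different acquisition chain's units), and the subgroup minimum
size for flagging. Every stochastic step (simulation, CV fold shuffling,
bootstrap) takes its seed from configuration, and identical inputs, config
and seed produce byte-identical reports.

The default problem sizes used by the test suite and the acceptance script
— a 144-patient cohort for headline metrics, ~2100 patients (~4800
signals) for distributional checks, 100–200 seeded replicates for
landmark-recovery and lasso-recovery rates — are chosen so Monte-Carlo
error is small relative to the asserted tolerances.

## Known limitations

* Single-beat analysis only: no multi-beat averaging, no arrhythmia or
  ectopy handling; atrially paced beats are analyzed as-is.
* The HF/LF split frequency and filter order for the original acquisition
  chain are not published; defaults are physiologically motivated
  stand-ins, exposed in configuration.
* HF-onset detection assumes a usable noise baseline at the start of the
  beat window; very early activation contaminates it (warned, not fixed).
* Legacy binary `.xls` feature tables are not readable (no installed
  reader); use CSV/TSV/XLSX.
* The synthetic cohort validates the statistical machinery, not clinical
  performance; see the structural simplifications above.
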