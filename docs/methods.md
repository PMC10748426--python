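# Methods

`fpcoma` implements a quantitative-EEG prognosis pipeline for comatose ICU
patients monitored with a limited frontoparietal montage: four scalp
electrodes (F3, F4, P3, P4) referenced to Cz, sampled at 250 Hz, recorded
for ≥ 30 min at rest. The pipeline turns each recording into a 48-entry
feature vector, compares favorable (60-day GOS ≥ 3) and unfavorable
(GOS ≤ 2) outcome groups, prunes amplitude-driven redundancy, and builds
logistic predictors of unfavorable outcome evaluated by stratified 3-fold
cross-validation. A synthetic cohort generator makes every stage testable
without clinical data.

## Preprocessing

Recordings are cut into non-overlapping 2-min epochs starting at sample 0;
the trailing remainder is discarded so every feature estimator sees the
same window length. Each epoch is baseline-calibrated by per-channel mean
removal (idempotent, the minimal reading of "baseline calibration"), then
bandpass filtered 0.1–40 Hz with a 4th-order Butterworth applied forward
and backward (zero phase; effective attenuation of a double pass). The
filter uses reflect padding of three time constants of the 0.1 Hz edge
(`3·fs/lo` samples) because the default short padding leaves edge
transients large enough to trip the artifact gate on high-amplitude
signals. An epoch is rejected when any channel contains any sample with
|amplitude| > 200 μV; the QC log records the offending channel and sample.
Rejection runs after filtering, following the stated processing order.
Re-referencing is out of scope: data are assumed recorded against Cz.

## Features (8 temporal + 16 frequency + 24 connectivity)

**Temporal.** RMS is the population standard deviation (after mean
removal); activity its square. Hjorth mobility is
`sqrt(var(x′)/var(x))` with `x′` the first difference scaled by the
sampling rate, which reproduces the continuous-time `2πf` for sinusoids;
complexity is `mobility(x′)/mobility(x)`. Both are reported missing (NaN),
not zero, for constant signals. Kurtosis is the non-excess standardized
fourth moment (normal → 3); skewness the third. Shannon entropy uses an
equal-width 64-bin amplitude histogram and natural log; the bin count is a
parameter because no estimator convention fixes it, and the value scale
depends on it.

The burst suppression ratio (BSR) is the fraction of the epoch spent in
the suppression state. Suppression is detected on the amplitude envelope —
a 100-ms moving average of |x| — staying at or below 5 μV for at least
0.5 s. The envelope and minimum-run requirements keep instantaneous
zero-crossings of large oscillations from counting as suppression; both
are configurable.

**Frequency.** Welch PSD (4-s Hann segments, 50% overlap, density
scaling; Parseval holds within ~5% for broadband noise). Band powers are
trapezoid integrals over δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz. Total power
is defined as δ+θ+α+β so the four band-to-total ratios sum to exactly 1.
`f_m` is the frequency of the PSD maximum in [0.5, 30] Hz. `f_h` is the
95% spectral edge within [0.5, 30] Hz (edge fraction configurable); note
that "upper cutoff frequency" has no unique definition, and the package
reports it in Hz.

**Connectivity**, for each of the 6 channel pairs: Pearson correlation;
mutual information from a 64×64 joint amplitude histogram (natural log,
marginals taken from the joint so the plug-in estimate is nonnegative;
clipped at 0); and two phase-synchrony metrics computed from analytic-
signal phases of the broadband (0.1–40 Hz) epochs — the phase-locking
value `PLV = |⟨e^{iΔφ}⟩|` and the phase-lag index
`PLI = |⟨sign(sin Δφ)⟩|`. Taking the sign of the *wrapped* phase
difference (equivalently of `sin Δφ`) is the standard PLI; the raw
difference of unwrapped phases drifts across ±π multiples and its sign is
not meaningful. PLI is 0 for symmetric/zero-lag phase distributions and 1
for a consistently one-sided lag, making it insensitive to
volume-conduction-like zero-lag coupling. Phases are computed once per
epoch on the full filtered band, since a single PLV/PLI per pair is
reported, not per-rhythm values.

**Aggregation.** Temporal and frequency features take the median across
the four channels within each epoch; connectivity is per-pair. Both are
then averaged over all retained epochs, skipping missing values and
recording how many epochs were excluded per feature.

## Statistics

For each feature, Shapiro–Wilk runs per group and Levene (mean-centred,
matching common statistical-package defaults) across groups at α = 0.05.
If both groups are normal with homogeneous variance, a pooled two-sided
t-test is used and groups are summarized as mean ± SD; otherwise a
two-sided Mann–Whitney U with tie-corrected normal approximation,
reported as the signed standardized z (positive when the favorable group
runs larger) with median (IQR) summaries. Benjamini–Hochberg step-up
correction is applied across all 48 features.

Because spectral band powers and several other features scale with overall
voltage, significant features (except RMS itself) are partially correlated
with the 60-day GOS controlling for RMS; features whose partial p ≥ 0.05
are pruned as amplitude proxies. The partial correlation is rank-based
(Spearman flavour) by default since GOS is ordinal; a Pearson flavour is
available by flag. Spearman correlations with GOS are reported for the
survivors.

Multiple correspondence analysis discretizes each continuous feature at
its within-cohort median (parameter-free and reproducible) and runs
indicator-matrix correspondence analysis via SVD. Reported discrimination
measures are the per-variable η² of the standardized object scores across
that variable's categories, the homogeneity-analysis definition; axis
signs are fixed so the unfavorable-outcome category has a positive
dimension-1 coordinate.

Prognostic models are maximum-likelihood logistic regressions of
unfavorable outcome (the positive class throughout). Stepwise selection is
forward with backward pruning, driven by likelihood-ratio χ² p-values at
p-enter 0.05 / p-remove 0.10 (standard package defaults), deterministic
given candidate order with ties broken by smaller p. Under perfect
separation the Newton solver fails; the fit falls back to L-BFGS, the
model is flagged, and odds-ratio CIs are reported as unbounded rather than
numeric artifacts. In cross-validation, a separated *training fold* would
drive the ML coefficients toward infinity and saturate the held-out
probabilities at exactly 0/1, destroying the rank information the merged
ROC pools across folds; separation-flagged fold fits therefore use a
lightly L2-penalized Newton fit (features standardized, intercept
unpenalized, α = 0.5) for prediction only. The reported odds-ratio tables
always come from the ML fit.

Cross-validation stratifies greedily on outcome × etiology cells, largest
cell first, dealing shuffled members over folds ordered by current load:
per-cell counts and overall fold sizes each differ by at most 1, and the
assignment is reproducible from its seed. Models are refit per training
set; held-out fold probabilities give per-fold sensitivity, specificity,
PPV, NPV and FPR (Wilson 95% CIs) at a probability cutoff of 0.5, and are
pooled across folds for the merged ROC. AUC uses the rank (Mann–Whitney)
formulation with tie handling; its 95% CI is DeLong's. Wilson, Wald (for
odds ratios) and DeLong were chosen as the standard CI methods for their
respective quantities and are labelled in output.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not biophysically realistic EEG — there is no head model, no calibrated
1/f background, and no per-band connectivity. Each patient is a parameter
profile: suppression fraction, amplitude scale, δ/θ/α/β variance mix,
per-pair coupling (strength, phase lag, phase jitter), and a seed derived
deterministically from the cohort master seed.

One channel is a sum of band-limited Gaussian noise components with
variances proportional to the band mix. Coupled pairs share a common
rhythm source; the second channel receives the source rotated by a
constant lag plus slowly varying phase jitter via the analytic signal, so
coupling strength and jitter control the measured PLI monotonically. A
common burst/suppression gate (exponential segment durations, mean
suppression run ≥ 0.7 s so runs register against the 0.5-s minimum)
multiplies all channels; suppression *attenuates* the ongoing activity to
a ~0.7 μV floor rather than replacing it with independent noise, so
inter-channel phase structure survives suppression as it does in cortex.
`amp_scale` sets the overall channel RMS (≈ amp/√2), so amplitude and
suppression fraction control separate observables — this keeps the four
headline features from being mechanically entangled and makes the
generator-to-estimator closure exact per parameter. A linear per-channel
rescale caps rare Gaussian crests at 170 μV so clean recordings always
pass the 200 μV QC gate (an artifact-injection flag adds a >200 μV
excursion for testing the gate itself).

Class defaults follow the observed contrast pattern: unfavorable patients
get more suppression (0.36 vs 0.19), lower amplitude (20.5 vs 31 μV),
a β-shifted mix (β weight 0.040 vs 0.012) and weaker, noisier F3–P4
coupling (strength 0.48 vs 0.70; jitter 1.00 vs 0.62 rad). Within-class
spreads (suppression SD 0.12, amplitude SD 8 μV, log-normal mix jitter
σ = 0.5, coupling SD 0.15) are wide enough that outcome classes overlap
as clinical cohorts do — single-feature discrimination lands well below
perfect — while standardized group contrasts stay large (≈ 1). The
default cohort size template is 39/20/10/7/5 patients at GOS 1–5
(22 favorable / 59 unfavorable); etiology labels follow the 6/0/11/1/4
and 19/4/22/9/5 per-class mixes.

What passing tests show — and do not show. End-to-end tests demonstrate
that the pipeline recovers planted contrasts of realistic effect size from
cohorts of this size and that combining complementary features improves
cross-validated discrimination. They do not validate the features against
clinical EEG morphology (spindles, epileptiform patterns, reactivity), and
absolute feature medians depend on generator conventions, not physiology.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 81 patients with one 2-min
epoch per patient (the generator's 30-min default is exercised at reduced
duration), 20 pipeline replicates in the test suite and 10 in the
acceptance script. Degenerate inputs are reported as missing rather than
coerced: constant channels (mobility, complexity, PCC, PLV, PLI), zero
total power (spectral ratios), |r| = 1 controls (partial correlation).
Histogram MI estimates are biased upward by binning for independent
signals (≈ 0.1 nat at 64 bins and 30 000 samples); tests bound rather
than zero it. EDF output quantizes to 16 bits over an integer physical
span so written and reloaded samples agree within one quantization step.

## Known limitations

The subgroup path (strokes, TBI) only re-runs the group comparison on a
subset flag; no subgroup models are fit. MCA normalization conventions
differ between packages; only the η²-based discrimination measures and
relative category geometry are contract, not absolute coordinates. The
Mann–Whitney statistic is reported as the standardized z, which is the
scale used in the cohort tables this layout mirrors; the raw U is not
printed. Entropy and MI values are bin-count dependent and comparable
only within a fixed configuration.
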