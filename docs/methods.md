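# Methods

This note documents the models, numerical conventions and design choices
behind `bgem`: a pipeline that screens for elevated blood glucose
(≥ 7.8 mmol/L, the post-load threshold of an oral glucose challenge) from
5-minute, 50 Hz wrist PPG plus four demographic covariates.

## Preprocessing

Raw device output is signed 16-bit; codes are mapped to amplitudes by
`code / 2^15`. Every downstream feature is either amplitude-invariant or
homogeneous in amplitude, so any linear DAC convention is equivalent; the
conventional full-scale normalization was chosen and is tested for odd
symmetry.

Filtering uses a fourth-order Chebyshev type-II band-pass, 0.3–4 Hz,
stopband attenuation 20 dB (configurable), applied forward–backward
(`sosfiltfilt`). Zero-phase application preserves the pulse landmarks the
waveform features depend on and doubles the effective attenuation
(≥ 40 dB at DC and 10 Hz). A consequence of the type-II design worth
knowing: the stopband is *equiripple*, so DC is attenuated to the design
floor, not to zero — a constant input leaves a residual of amplitude
≈ 10^(−2·20/20) = 0.01.

Outliers are flagged by a single global z-score rule (|x−mean|/SD > 3,
computed over the whole filtered record, not windowed) and each flagged
sample is replaced by its nearest unflagged neighbour, ties broken toward
the earlier sample. Repair therefore never introduces values outside the
range of the unflagged samples. Constant (zero-variance) records are
rejected rather than passed through. The repaired signal feeds *all*
feature families, not only HRV.

## Beat detection

Systolic peaks: prominence-thresholded local maxima with a 0.25 s
refractory distance (240 bpm ceiling); the prominence threshold adapts to
the record as 0.5 × the median rolling (2 s) SD. Onsets are the local
minima between consecutive peaks. IBIs are peak-to-peak (peaks are the
robust landmark in wrist PPG, where the dicrotic notch is usually
undetectable) and screened to 250–2000 ms before HRV analysis. Windowed
heart rate counts peaks per non-overlapping 10-s window (× 6 → bpm);
empty windows are invalid and the trailing partial window is discarded.

## Feature catalogue (248 entries)

The catalogue object is the single source of truth for identifiers,
ordering and family boundaries: F1–F31 HRV time domain, F32–F44 Welch
spectral, F45–F57 AR spectral, F58–F71 nonlinear, F72–F81 heart rate,
F82–F84 CWT, F85–F196 waveform (14 quantities × 8 statistics), F197–F206
Kaiser–Teager energy, F207–F223 log energy, F224 sample entropy, F225–F244
multiscale entropy, then Age, Gender (female = 0, male = 1), BMI,
Family_history (no = 0, yes = 1). The compositions *inside* blocks are the
package's canonical choices (the block boundaries and the named features —
Welch_hf_rel, AR_hf_rel, A_FE_mean, A_ratio_mean/max, A_Pulse_iqr,
KTE_skew, LOG_std, MSE_sum_13_14 — are fixed); the catalogue is data-driven
so an alternative mapping can be swapped in without touching any code that
consumes it.

Conventions that matter:

- HRV is computed on one 5-minute frame (shorter records are analysed
  whole, with a warning). SDSD is defined as the SD of the *absolute*
  successive differences, so a strictly alternating IBI series has
  SDSD = 0 while RMSSD equals the alternation step.
- Spectral features: the IBI series is linearly interpolated onto a 4 Hz
  tachogram; Welch uses 256-sample (64 s) segments with 50 % overlap; the
  AR spectrum uses Yule–Walker coefficients of order 16 (MLE/biased
  autocovariance for stationarity). Bands: VLF 0.0033–0.04, LF 0.04–0.15,
  HF 0.15–0.4 Hz. Relative powers are fractions of total (≤ 0.4 Hz) power;
  normalized LF/HF are fractions of LF+HF.
- Poincaré SD1 is defined as RMSSD/√2 exactly (no mean subtraction), and
  SD2 = √(2·SDNN² − SD1²), so the algebraic identity SD1 = RMSSD/√2 holds
  for any IBI series. CSI = SD2/SD1, CVI = log10(16·SD1·SD2),
  modified CSI = (4·SD2)²/(4·SD1).
- DFA α1 uses box sizes 4–16, α2 16–64 (NaN below 50/64 IBIs — never hit
  by 5-minute records); Higuchi FD uses k_max = 10; the correlation
  dimension is a Grassberger–Procaccia slope at embedding dimension 2.
- Energy measures use non-overlapping 5-s frames ("sliding" stride equal
  to the frame length). KTE statistics are computed per frame and averaged
  across frames. Log energy is E_log = Σ log(x² + ε), ε = 1e−12, so an
  all-zero frame contributes a finite floor instead of −∞; LOG_ar1…7 are
  Yule–Walker AR(7) coefficients of the E_log sequence in the convention
  x_t = a₁x_{t−1} + … + e_t.
- Sample entropy uses m = 2 and r = 0.1 × SD (note: deliberately 0.1, not
  the more common 0.2). Template pairs are counted with a k-d tree under
  the Chebyshev metric — O(N log N)-ish, which makes full-record
  (N = 15000) evaluation take well under a second — and the count is
  verified in the tests against a direct O(N²) counter. When no
  (m+1)-match exists the value is capped at ln(n_pairs), the −ln of the
  smallest resolvable conditional probability.
- MSE: SampEn of non-overlapping block means at τ = 8…14, with r fixed
  from the scale-1 SD (per-scale r is a config option). The 20-entry block
  is the 7 per-scale values, 6 adjacent-scale sums (incl. MSE_sum_13_14),
  6 adjacent-scale means, and the grand mean. Records with fewer than 240
  pulses record the whole block as missing (NA) rather than as unreliable
  numbers; this is the only block allowed to be missing.
- Waveform geometry per pulse (onset → peak → next onset): RT/FT are times
  to/from the peak; RP/FN are magnitudes relative to the bounding onsets;
  areas integrate the segment above the chord joining the two onsets
  (trapezoidal); A_ratio = AUR/A_FE. Pulses with non-positive magnitudes
  or areas (artifact remnants) are skipped; at least 10 valid pulses are
  required.

## Ensemble feature selection

Six rankers each nominate 30 features: ANOVA F, mutual information,
dispersion ratio (arithmetic/geometric mean of the min-shifted positive
feature), RFE around an L2 logistic regression (step 5), L1 logistic
regression (penalty relaxed until ≥ 30 nonzero coefficients; ranked by
|coef|), and XGBoost gain importance. Features nominated by ≥ 2 rankers
survive the vote, ranked by vote count, then mean within-method rank, then
catalogue order; greedy pruning then drops survivors with |Pearson r| > 0.9
against an already-kept feature. Constant columns rank last by convention.
NaN rows (missing MSE blocks) are median-imputed by default (row-dropping
is a config option). A `force_include` option appends named features (e.g.
a covariate of interest such as gender) regardless of votes. Selection is
run once on the full matrix by default, mirroring common practice in this
setting; for leakage-free protocols the selector composes with sklearn
Pipelines inside CV.

## Evaluation

Stratified 10-fold CV (group-aware when repeated measurements per subject
are given, so a subject never straddles folds). Metrics are computed per
fold and aggregated as mean ± SD; the per-fold G-mean is √(Se·Sp) of that
fold (fold-averaging a concave statistic can only lower it relative to
aggregating first — a property the tests pin down). Undefined ratios
(zero denominators) are reported as 0 and flagged. Default
hyperparameters: SVM-RBF C = 1, γ = "scale"; kNN k = 5; RF 500 trees;
XGBoost/LightGBM 200 trees; scale-sensitive models are standardized inside
a Pipeline. No resampling is applied for class imbalance by default — the
metric set is imbalance-robust — and every stochastic component is seeded.

## Shapley explanation

Coalition values are interventional: v(S) = mean over a background matrix
of the score with the explained sample imposed on S. The explained score
is the decision margin for SVMs and the positive-class probability for
probabilistic models. With ≤ 12 features (the regime after selection)
coalitions are enumerated exactly and the efficiency, dummy and symmetry
axioms hold to machine precision (tested against an independent
permutation-definition oracle); beyond that, seeded permutation sampling
is used, and exact mode refuses > 20 features.

## Serial combination of repeated measurements

Assuming conditional independence of k repeats, OR (positive if any):
se' = 1−(1−se)^k, sp' = sp^k; AND (positive only if all): se' = se^k,
sp' = 1−(1−sp)^k. OR never lowers sensitivity and never raises
specificity; AND is the mirror — the tests verify this universally on a
grid and against Monte-Carlo simulation (10⁵ subjects, ±2 %).

## Synthetic cohort generator

The generator emulates what the pipeline needs to see, not hemodynamics:
per beat, a gamma-shaped pulse (shape κ = rise/decay, peak 1 at the rise
time) rendered at onsets driven by sinusoidal LF (0.1 Hz) + HF (0.3 Hz)
IBI modulation (total depth 40 ms RMS, split by a per-subject HF fraction)
plus 5 ms jitter; respiratory baseline (0.25 Hz, amplitude 0.3 of pulse
height — below the filter passband by design); white sensor noise
(SD 0.03); a weak AR(1) (ρ = 0.9) correlated-noise floor; Poisson spike
artifacts (0.5/min at 8 SD); per-subject lognormal gain. Defaults: n = 400
subjects, prevalence 0.5, 300 s at 50 Hz, HR 72 ± 7 bpm. Glucose is drawn
from truncated normals — normal class 5.5 ± 0.8 on (3.5, 7.8), elevated
9.5 ± 1.5 on [7.8, 20) — so the labelling rule reproduces the intended
class. One global seed fans out to per-subject seeds via SeedSequence
spawning; cohorts regenerate records lazily and deterministically.

**Class effects.** The strong configuration shifts the elevated class by
hf_rel_delta = 0.2 (target HF fraction of the tachogram), a_ratio_delta
= 0.3 (pulse morphology), mse_delta = 0.3 (coarse-scale entropy via the
correlated-noise floor), plus age +6 y, BMI +1.5 kg/m², family-history
probability +0.2. Two mappings deserve note:

- *Morphology*: the zero-phase band-pass substantially symmetrizes the
  rendered pulse, so a literal 0.3 shift of AUR/AUF is not reachable by
  any plausible rise-time change alone. The dial therefore moves both
  shape levers (rise +0.23 s and decay −0.10 s per unit), which yields a
  smaller absolute shift of A_ratio but a strong standardized effect
  (Cohen's d ≈ 2 for A_ratio_mean at the strong setting).
- *Entropy*: mse_delta scales the AR(1) noise SD (+0.10 per unit); its
  correlation time (~10 samples at 50 Hz) survives coarse-graining at
  τ = 8–14 and raises the coarse-scale SampEn (d ≈ 2–4).

The twelve features these effects target (the ground truth for recovery
checks) are the Welch/AR relative and normalized HF powers, A_ratio
mean/median, RT/FT mean, and five MSE composites.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real pulse-morphology variability (dicrotic
activity, reflected waves), non-stationary autonomic state, true
glucose–physiology coupling (effects are injected by construction),
realistic motion-artifact morphology, device quantization beyond the DAC,
and demographic correlation structure. End-to-end results on this cohort
demonstrate that the pipeline *recovers what was put in* at the stated
effect sizes; they are not clinical performance estimates.

## Problem sizes and numerical choices

The bundled end-to-end checks use n = 400 subjects at 5 minutes each
(≈ 0.5 s extraction per record), 10-fold CV, and an N = 15000 entropy
fixture — sizes chosen so the whole suite runs comfortably on one CPU.
Degenerate inputs fail loudly (constant signals, all-flagged masks,
single-class folds, zero-variance series) rather than producing silent
numbers; the few documented exceptions (CV of a zero-mean series → 0,
SampEn cap when no template extends) are conventions, each noted at the
definition site.
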