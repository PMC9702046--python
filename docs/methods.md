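# Methods

## Scope

`dwiadc` implements a complete quantitative DWI response-biomarker
analysis: phantom simulation, voxel-wise ADC mapping, ROI histogram
reduction, group statistics with ROC cut points, and dichotomised
survival analysis. Masks are inputs (no segmentation), scans are analysed
independently (no registration), and only the mono-exponential model is
fitted to data — the bi-exponential IVIM model is used exclusively to
*generate* phantom signal.

## Phantom generator

Each synthetic patient is a paired pre/post-treatment 4-D DWI volume of a
spherical lesion in a free-water-like background, plus time-to-event
outcomes.

**Signal model.** Lesion voxels follow the IVIM bi-exponential
`S(b) = S0·(f·e^(−b·D*) + (1−f)·e^(−b·D))`. Defaults: b ∈ {0, 100, 150,
250, 500, 750} s/mm² (the alternate scheme {0, 50, 100, 250, 500, 750} is
provided as `B_VALUES_ALTERNATE`; both resolve correctly under the high-b
subset rule b ≥ 100), S0 = 200 a.u., f = 0.17, D* = 25×10⁻³ mm²/s,
median tissue D = 1.20×10⁻³ mm²/s. The (f, D*, D) triple was chosen so the
noiseless OLS fit gives ADC_all ≈ 1.35×10⁻³ and ADC_b100 ≈ 1.22×10⁻³
mm²/s — the baseline regime gap a vascular bladder tumour shows, with f in
the 10–20% range typical of IVIM estimates in such tumours.

**Heterogeneity.** Per-voxel D is log-normal with median D and coefficient
of variation 0.15 (positive support, right-skewed histograms comparable to
tumour ADC maps). The default lesion radius is 5 voxels at 2 mm isotropic
(≈ 515 voxels ≈ 4 cm³, the order of a median bladder lesion).

**Treatment effect.** The post scan multiplies every lesion voxel's D by
(1 + effect); the patient's effect is drawn normally around the group mean
(SD 0.10 responders, 0.05 poor responders — wide enough that some patients
decrease, as real cohorts show). Group means 0.244 / 0.092 were obtained by
root-finding so the *fitted* all-b ADC rises by 21.7% / 8.23% in the
noiseless limit: the perfusion compartment does not respond to treatment,
so the relative change in fitted ADC is attenuated below the change in D,
and the design targets are on the fitted scale. The corresponding high-b
changes come out near 24% / 9% — slightly larger than the all-b changes,
the same ordering the fitted regime comparison produces on real tumours.

**Noise.** Rician magnitude noise: `|S + n₁ + i·n₂|` with independent
Gaussian n of standard deviation S0/SNR per voxel and b-value; default
SNR 50. At this level the fitted-ADC bias in ROI voxels is under 3%
(checked by simulation). Setting `snr = inf` disables noise for analytic
checks, which together with `perfusion_fraction = 0` makes every fit
exact.

**Survival.** Event times are exponential with a per-endpoint baseline
hazard (reference = poor response) and a multiplicative hazard ratio for
responders: OS 0.045/month × HR 0.40, bladder-cancer-specific 0.030 × 0.26,
progression 0.060 × 0.16, cystectomy 0.040 × 0.19; censoring is an
independent exponential clock at 0.008/month. Bladder-cancer death and
other-cause death are competing exponentials whose rates sum to the OS
hazard, so bladder-specific events are a subset of OS events while each
endpoint's marginal hazard equals its configured rate. The baseline OS
hazard puts the mixed-cohort median OS near 30 months. The clinical table
carries both raw outcome columns (death date/cause, progression and
cystectomy dates, last follow-up) and the derived per-endpoint
(time, event) pairs; `derive_endpoints` applies the censoring rules to the
raw columns (non-bladder and unverified deaths censor the cancer-specific
endpoint at death; missing progression/cystectomy dates censor at last
follow-up) and validates either layout.

**What the phantom does not emulate.** Anatomy, partial-volume edges,
motion/distortion artefacts, scanner/vendor differences, spatially
correlated noise, multi-focal disease (multiple ROI labels are supported
but not generated), and any dependence of survival on lesion biology
beyond the response group. Passing tests therefore demonstrate the
*statistical machinery* recovers designed effects under idealised imaging,
not that the thresholds transfer to real scanners.

## ADC mapping

Unweighted OLS of ln S on b per voxel; ADC = −slope, S0 = e^intercept —
the deterministic, closed-form standard for clinical ADC. A voxel with any
non-positive signal in the chosen subset is marked invalid rather than
clipped (avoids log-domain bias); negative fitted ADC is returned and
counted in QC but excluded from histogram features. The b-subset rule is
b ≥ min_b with at least two distinct b-values; `all` (min_b = 0) and
`high_b` (min_b = 100) are predefined. Nonlinear least squares is used
only as a test oracle: at SNR 50 the two estimators' median fitted ADC
agrees to well under 1%, while their per-draw scatter (they weight the
same noise differently) is a first-order-in-noise effect of a few
percent — an estimator property, not a defect.

## Histogram features

Valid, non-negative ADC voxels are quantised to bin centres at width
1×10⁻⁶ mm²/s (three orders of magnitude below the value scale, so binned
and raw statistics agree to within one bin) before computing the mean,
percentiles (linear interpolation on the binned empirical distribution),
bias-corrected Fisher–Pearson skewness and excess kurtosis. Zero-variance
ROIs report skew = kurtosis = 0 by convention. `%Δ = 100·(post − pre)/pre`
is applied verbatim to every feature, including negative-baseline skew and
kurtosis where the sign is counterintuitive; a zero baseline flags the
percent change as undefined rather than repairing the formula.

## Response statistics

- Mann–Whitney U: exact enumeration for combined n ≤ 12 without ties;
  otherwise the tie-corrected normal approximation *without* continuity
  correction, so the two-group Kruskal–Wallis chi-square p is identical —
  one consistent asymptotic family across the package.
- Bonferroni: p_adj = min(1, m·p) with m = 8 (the features tested per
  regime block) by default, exposed in config.
- ROC: empirical curve over all distinct thresholds under the rule
  "score > c predicts response"; AUC by trapezoid, identically
  U/(n₊·n₋); p-value against AUC = 0.5 from the tie-corrected normal
  null of U; the significance rule is AUC > 0.6 *and* p < 0.05.
- Youden cut point: J maximised over distinct observed scores, ties broken
  toward the smallest threshold (maximises sensitivity; recorded so
  results are reproducible).
- Predictive values: sensitivity/specificity/PPV/NPV in percent with
  exact Clopper–Pearson (beta-quantile) 95% CIs — the interval family that
  reproduces published exact CIs such as 9/10 → 55.5–99.7%.
- `reconstruct_confusion` rebuilds integer confusion counts from printed
  sensitivity/specificity (round half away from zero), the bridge that
  lets PPV/NPV be verified from a published table without patient data.

## Survival analysis

Kaplan–Meier product-limit curves (lifelines) with the median defined as
the earliest time S(t) ≤ 0.5, left undefined under heavy censoring rather
than extrapolated; median CIs by the log–log (exponential Greenwood)
transform. The two-group log-rank statistic is accumulated in-package from
the per-event-time 2×2 hypergeometric sums (events precede censoring at
tied times) and cross-checked against lifelines in the tests. The hazard
ratio comes from a univariate Cox partial-likelihood fit with a Wald 95%
CI; lifelines' Efron tie handling is used — phantom event times are
continuous, so tie corrections never engage — and the simple
(O/E)/(O/E) estimate is reported alongside as a cross-check. When all
events fall in one group the partial-likelihood estimate diverges and the
HR is reported as undefined (nan) rather than a spurious number.
Dichotomisation uses "score > cut point = favourable group" and errors on
an empty group.

## Pipeline

`run_all` executes simulate (or load) → fit → features → group statistics
→ cut points → dichotomised survival. Intermediates are written to disk
(NIfTI volumes with FSL-style `.bval` sidecars, CSV tables, JSON manifest
and report) so any stage can be re-run from saved artifacts; every report
carries the seed and a config hash, and identical config + seed reproduce
byte-identical reports. All analysis-relevant constants (b-subsets, bin
width, alpha, Bonferroni family size) appear in the config echo — no
silent defaults.

## Problem sizes

Defaults were chosen to keep a full cohort analysis interactive: 24³
voxel volumes (lesion radius 5) give a 48-patient end-to-end run in
about a second. The Monte-Carlo recovery studies use 14³ volumes with the
same lesion radius — the ROI, which is all the analysis sees, is
unchanged — with 100 cohorts for effect-detection and n = 500/group for
hazard-ratio recovery; the type-I-error check uses 10⁴ replicates at the
38 vs 10 split.

## Known limitations

- The phantom's idealisations (above) mean absolute cut-point values from
  synthetic runs should not be read as clinically meaningful thresholds.
- OLS-on-log weights high-b (low-signal) points more than nonlinear
  fitting; at low SNR this shifts individual-voxel estimates although ROI
  summaries remain stable.
- The Rician noise floor biases low signals upward; at SNR ≥ 50 and
  b ≤ 750 s/mm² the effect on fitted ADC is below 3%, but the generator
  should not be pushed to much higher b·D or much lower SNR without
  revisiting the bias checks.
- Survival generation assumes proportional hazards and independent
  censoring; violations of either are outside the generator's design
  space, matching the assumptions of the log-rank/Cox analysis it feeds.
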