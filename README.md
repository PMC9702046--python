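# dwiadc

Quantitative diffusion-weighted MRI (DWI) analysis for assessing tumour
response to treatment, built around the bladder-cancer / neoadjuvant-
chemotherapy (NAC) setting: voxel-wise apparent diffusion coefficient
(ADC) mapping from multi-b-value DWI, ROI histogram features, pre/post
change biomarkers with ROC-derived cut points, and dichotomised
time-to-event analysis. A synthetic IVIM phantom cohort generator stands
in for patient scans, so the entire pipeline is testable and reproducible
without any imaging data.

Intended users: imaging scientists and biostatisticians developing or
validating quantitative DWI response biomarkers.

## The model

Signal in each voxel is reduced to an ADC by ordinary least squares of
log-signal on b under the mono-exponential model

    S(b) = S0 · exp(−b · ADC)

fitted twice per scan: over all b-values (`ADC_all`) and over b ≥ 100 s/mm²
(`ADC_b100`), the perfusion-insensitive regime. The phantom generates the
signal from the bi-exponential intravoxel-incoherent-motion (IVIM) model

    S(b) = S0 · ( f · exp(−b · D*) + (1 − f) · exp(−b · D) )

with perfusion fraction `f` and pseudo-diffusion coefficient `D* ≫ D`, which
is why the all-b fit systematically exceeds the high-b fit at baseline.

Per lesion ROI, the ADC distribution (binned at 1×10⁻⁶ mm²/s) is summarised
by mean, 10th/25th/50th/75th/90th percentiles, skewness and excess
kurtosis. Treatment change per feature is ΔADC = post − pre and
%ΔADC = 100 · (post − pre)/pre. Groups are compared by Mann–Whitney U
(Bonferroni-adjusted); predictive thresholds come from empirical ROC
curves (significant when AUC > 0.6 and p < 0.05) at the Youden-index
maximum J = max(sensitivity + specificity − 1), reported with exact
Clopper–Pearson 95% CIs; survival endpoints (OS, bladder-cancer-specific
survival, PFS, time to cystectomy) are contrasted between biomarker-
dichotomised groups by Kaplan–Meier curves, log-rank test and a Cox
hazard ratio.

## Worked example

```python
import dwiadc as d
from dwiadc.pipeline import RunConfig, run_all

report = run_all(RunConfig(seed=1, phantom=d.PhantomConfig(seed=1)))

c = report.comparisons
row = c[(c.family == "percent_delta") & (c.regime == "high_b")
        & (c.feature == "mean")].iloc[0]
print(f"%change in mean ADC (high-b): responders {row.response_median:.1f}%, "
      f"poor responders {row.poor_median:.1f}%, p = {row.p_value:.1e}")

cp = report.cut_points
sel = cp[(cp.family == "percent_delta") & (cp.regime == "high_b")
         & (cp.feature == "p75")].iloc[0]
print(f"75th-percentile %change cut point: > {sel.cut_point:.1f}% "
      f"(AUC {sel.auc:.2f}, sens {sel.sensitivity:.1f}%, spec {sel.specificity:.1f}%)")
```

prints

```
%change in mean ADC (high-b): responders 22.1%, poor responders 7.1%, p = 4.3e-06
75th-percentile %change cut point: > 13.5% (AUC 0.98, sens 89.5%, spec 100.0%)
```

i.e. on the default 48-patient phantom cohort (38 responders, 10 poor
responders, SNR 50) the relative increase in mean high-b ADC after
treatment is about three times larger in responders, and a
75th-percentile %ΔADC threshold of roughly +13% separates the groups with
high specificity. `report.survival_contrasts` holds the per-endpoint
log-rank p and hazard ratio for the cohort dichotomised at that cut point.

The same run is available from the shell:

```sh
dwiadc run-all --seed 1 --out results/run1
dwiadc simulate --seed 7 --out phantom_data   # NIfTI volumes + CSV + manifest
```

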