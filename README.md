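# fwctex

Texture analysis of **fractional water content (FWC)** parametric maps from
PET/MRI Dixon acquisitions, with the downstream statistics a prognostic
imaging-biomarker study needs: inter-operator reproducibility QC,
correlation screening against functional imaging metrics, optimal-cutpoint
survival analysis with Cox modeling, and gene-mutation association.

## The problem

Oncological PET/MRI routinely acquires a two-point Dixon sequence that
separates water and fat signal into two co-registered images. Dividing the
water image by the water + fat sum yields a per-pixel **fractional water
content** map, FWC = W/(W+F) ∈ [0, 1] — the complement of the clinically
used signal fat fraction (FWC = 1 − FF). The spatial *distribution* of
water inside a tumor carries biological information that the mean value
alone misses. `fwctex` quantifies that heterogeneity with
**filtration-histogram texture analysis**: the FWC image is band-pass
filtered with a Laplacian-of-Gaussian kernel

σ_px = SSF / pixel-spacing,  LoG(r) = −(1/πσ⁴)(1 − r²/2σ²) e^(−r²/2σ²)

at spatial scale factors SSF ∈ {2, 3, 4, 5, 6} mm (fine → coarse), and six
first-order statistics — mean, SD, entropy, mean of positive pixels (MPP),
skewness, excess kurtosis — are computed over the tumor ROI of each
filtered image plus the unfiltered one (SSF 0): **36 features** per ROI.

The statistical stages mirror a typical pilot-study design (n ≈ 30):

1. **QC** — per-feature two-way random-effects absolute-agreement ICC(2,1)
   between two independent ROI operators; features with ICC ≤ 0.75 are
   dropped, retained features are averaged across operators.
2. **Screening** — Spearman rank correlation of each retained feature
   against SUVmax, SUVmean, TLG, ADC mean/skewness/kurtosis;
   Benjamini–Hochberg FDR at q = 0.1.
3. **Survival** — each marker dichotomized at the cutpoint minimizing the
   two-group log-rank p over admissible splits (≥ 10% of subjects per
   group); the best significant marker per modality feeds a forward
   stepwise Cox model (entry by partial-likelihood score statistic at
   p < 0.05, Efron ties) including pairwise interactions.
4. **Radiogenomics** — Mann–Whitney U (exact by enumeration for combined
   n ≤ 12) on total mutation counts between the prognostic groups of the
   top texture marker, plus per-gene 2×2 Fisher exact tests.

Because clinical Dixon cohorts are rarely shareable, the package ships a
**synthetic cohort generator**: random smooth tumors at FWC ≈ 0.88 with
Gaussian "pockets" of elevated water content (the heterogeneity the
filtration step highlights), jittered operator contours, and clinical /
mutation tables with configurable couplings — a negative rank correlation
between coarse-scale MPP and TLG, a hazard ratio for the high-texture
group, and a mutation-count contrast between prognostic groups. All
couplings set to zero give an exact null cohort for calibration.

## Worked example

```python
from fwctex import CohortConfig, generate_cohort, run_full_analysis

cohort = generate_cohort(CohortConfig(seed=1))      # 30 patients
result = run_full_analysis(cohort)

print(len(result.icc.retained_features))            # 35
sig = result.correlations.significant()
top = sig.loc[sig.r_s.abs().idxmax()]
print(top.feature, top.metric, round(top.r_s, 3))   # mpp_ssf6 tlg -0.703
best = min(result.survival.significant(), key=lambda e: e.p)
print(best.parameter, best.direction, f"{best.p:.2e}")
                                                    # mpp_ssf5 high_poor 2.33e-07
```

Reading: of the 36 texture features, 35 pass the inter-operator ICC > 0.75
gate. The strongest TLG correlate is MPP at the coarse 6 mm scale with
r_s = −0.703 — tumors with more/brighter water pockets have lower total
lesion glycolysis, the direction the generator encodes (target Spearman
−0.55; a single n = 30 draw scatters around it). Several texture markers
split survival, with the high-texture group faring worse
(`high_poor`); the forward-score Cox stage and the mutation stage then run
on the dichotomized markers.

The same workflow is available from the shell:

```
fwctex simulate --out cohort/ --seed 1
fwctex fwc --water cohort/P000_water.nii.gz --fat cohort/P000_fat.nii.gz --out fwc.nii.gz
fwctex texture --fwc fwc.nii.gz --mask cohort/P000_mask_op1.nii.gz --out features.csv
fwctex analyze --cohort cohort/ --fdr 0.1
fwctex run --simulate --seed 1 --out run/     # everything, with a checksummed manifest
```

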