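# Methods

## FWC parametric maps

A Dixon slice pair (water W, fat F, pixel spacing in mm) maps to
FWC = W/(W+F). Pixels with W+F = 0 (air, background) have no defined
fraction; they are flagged invalid and **excluded** from every statistic
rather than zero-filled — zero-filling would bias the mean and MPP of any
ROI touching background. On valid pixels the complement identity
FWC + FF = 1 holds to machine precision, and FWC is invariant to a common
rescaling of both channels, so arbitrary scanner gain does not matter.

The automated threshold ROI keeps every pixel ≥ fraction × global maximum
(default 0.42, the routine PET lesion-segmentation setting) with no
connected-component filtering. Masks live on the image grid; no
resampling between grids is performed.

## Filtration-histogram texture

The commercial implementations of this technique leave several numerical
choices unpublished; this package fixes them as follows and records them
in the output metadata, flagged as best-effort reconstructions:

* **Scale mapping** — σ_px = SSF_mm / pixel_spacing_mm per axis
  (anisotropic-capable), so the SSF is the physical feature scale in mm.
* **Kernel** — the Laplacian of the axis-aligned Gaussian sampled at
  integer offsets, truncated at 4σ, then mean-subtracted so the discrete
  weight sum is exactly zero. Zero DC makes constants map to zero and all
  SSF > 0 features invariant to additive intensity offsets. For equal
  spacings each tap equals −(1/πσ⁴)(1 − r²/2σ²)e^(−r²/2σ²) up to the DC
  shift.
* **Boundary** — the whole image is filtered before masking (prevents
  mask-edge ringing from dominating ROI statistics), with mirror padding
  applied by repeated reflection so coarse kernels remain defined on
  small fields. Convolution uses direct or FFT evaluation, whichever is
  cheaper; outputs within roundoff of zero are snapped to exactly zero so
  constant regions stay analytically degenerate (SD = entropy = 0, no
  spurious "positive" pixels for MPP). Invalid pixels are filled with the
  valid-region mean for the convolution only, so a zero-signal frame does
  not fabricate step edges.
* **Statistics** — mean; sample SD (n−1); Shannon entropy in bits of the
  64-equal-width-bin histogram over the ROI's own [min, max] (0 if all
  values coincide); MPP over strictly positive values (missing if none);
  adjusted Fisher–Pearson skewness; excess kurtosis. Skewness/kurtosis
  are reported missing below their minimum n (3 / 4) or at zero spread;
  missing features are handled pairwise downstream.

Scaling behaviour (checked by tests): multiplying intensities by k > 0
scales mean/SD/MPP by k and leaves entropy, skewness and kurtosis
unchanged; filtration is translation-equivariant away from boundaries.

## Statistical stages

**ICC QC.** ICC(2,1) — two-way random effects, absolute agreement, single
measure — from the mean-squares decomposition:
(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n). The framework for grading
gives good agreement above 0.75 and excellent above 0.9; features at
ICC ≤ 0.75, with fewer than 3 complete pairs, or with zero total variance
are dropped, and retained features are replaced by the per-patient
operator mean. Re-running QC on the averaged table retains everything
(ICC of identical raters is 1), so the gate is idempotent.

**Correlation screening.** Spearman with average ranks and the
t-approximation p-value, each retained feature against the six functional
metrics. BH step-up control at q = 0.1 is applied per metric across
features by default; pooling all feature × metric tests globally is a
config option (`bh_scope="global"`) since either reading of the
multiplicity scope is defensible.

**Optimal-cutpoint survival.** Candidate thresholds are midpoints between
consecutive distinct values; splits leaving fewer than
`min_group_frac · n` (default 10%) per group are inadmissible, which
avoids degenerate 1-vs-(n−1) splits while still allowing the uneven
splits that markers like TLG produce. The reported p is the exact minimum
over admissible candidates (oracle-scan equivalence is tested), carries
no multiplicity correction, and is flagged exploratory in the report
metadata — optimized cutpoints overstate significance by construction.
The poor-prognosis direction is the sign of the partial-likelihood score
for the high-group indicator at the null (positive = more deaths than
expected above the threshold).

**Cox model building.** Candidates are the best significant univariate
marker per modality (texture / FDG / ADC), dichotomized at their optimal
thresholds, plus all pairwise products of the 0/1 indicators. Forward
entry picks the largest partial-likelihood score statistic (evaluated at
the current MLE with the new coefficient pinned at zero; Efron ties) and
admits it if the 1-df score p < 0.05; the loop stops when none qualify.
Included terms report HR with Wald 95% CI; excluded terms report their
score statistic and p against the final model — the score machinery is
implemented from the Efron partial-likelihood derivatives because
off-the-shelf fitters expose only Wald/LR quantities. Monotone likelihood
(complete separation, e.g. a zero-mortality group — common with optimized
cutpoints on small cohorts) is rescued with a small ridge penalty and the
affected estimates are flagged `unstable`.

**Mutation stage.** The most significant prognostic texture marker
(deterministic tie-break: coarsest SSF, then alphabetical statistic)
defines good/poor groups. Total mutation counts are compared by
two-sided Mann–Whitney U — exact by enumeration of all group-label
assignments for combined n ≤ 12, which conditions correctly on ties;
tie-corrected normal approximation without continuity correction
otherwise. Per-gene 2×2 tables get the two-tailed Fisher exact test with
the conditional-MLE odds ratio (0/∞ allowed and flagged); zero-margin
tables are rejected.

## Synthetic cohort generator

The generator emulates the data products of a ~30-patient prospective
PET/MRI study; defaults are the study conditions, chosen once:

* **Geometry** — 128×128 grid at 0.78×0.78 mm. Lesions are random smooth
  blobs (thresholded low-pass noise over an elliptical core) with areas
  ~1100–6000 px, matching reported tumor ROI sizes (mean 1768, range
  445–6233 px). Tumor FWC 0.88 (the reported cohort mean), surrounding
  tissue 0.80, with a Gaussian partial-volume taper (σ = 3 px) at the
  boundary. The taper matters: the coarse 6 mm kernel spans ~31 px, and a
  hard step edge would dominate the band-pass response; with the taper
  the coarse-scale signal is pocket-driven. A 2 px zero-signal frame
  exercises the invalid-pixel path.
* **Heterogeneity** — 2–14 Gaussian pockets of elevated FWC per tumor
  (radii 2–6 mm, spanning the SSF scales; amplitudes 0.05–0.10), centers
  uniform over the lesion. The clean FWC field is built first and then
  converted to water/fat via a per-pixel total-signal field
  (W = FWC·S, F = (1−FWC)·S), so FWC inversion recovers the designed
  pattern exactly; Gaussian channel noise (sd 1, i.e. 1% of S, truncated
  at 0) is added to each channel separately, matching how Dixon noise
  propagates into the ratio.
* **Latent texture driver** — the coarse-scale (SSF 6) MPP of the
  noise-free FWC map over the true lesion, computed with the package's
  own texture engine at generation time. Coupling clinical variables to
  this driver rather than to, say, the pocket count means the configured
  correlations refer to the quantity the pipeline actually measures;
  measured MPP tracks the driver at Spearman ≈ 0.9 under default noise
  and ROI jitter, so a configured coupling of −0.55 is recovered at about
  −0.50 on measured features.
* **Operator ROIs** — integer translation plus random dilation/erosion of
  the true contour, each bounded by `roi_jitter_px` (default 2); a jitter
  that empties the mask retries at half amplitude with a warning.
  Default jitter gives inter-operator Dice ≈ 0.85–0.95.
* **Clinical table** — TLG is rank-coupled to the driver through a
  Gaussian copula (target Spearman −0.55; |ρ| ≥ 1 rejected) with a
  lognormal marginal placing ~10% of patients above 378. SUV and ADC
  metrics are drawn uncoupled (the study found no significant texture
  correlates for them); their marginals are plausible clinical ranges.
  Clinical stage is drawn 1–4 with slightly adverse odds for the
  high-driver group.
* **Survival** — exponential, baseline 0.004 events/month for the
  low-driver half, log hazard ratio 1.5 for the high-driver half
  (≈ 23% deaths by the horizon), administrative censoring at the
  32-month follow-up maximum plus random early censoring of a 20%
  fraction at Uniform(5, 32) months.
* **Mutations** — per-gene Bernoulli over a fixed 12-gene panel (RAS/RAF/
  PI3K pathway + APC exon groups) with per-gene rate `rate/12`;
  rate 7 for the good-prognosis (low-driver) group and 1.5 for the poor
  group reproduces the designed count medians (7 vs ~1). By default only
  12 of 30 patients carry mutation data, mirroring partial profiling.
* **Determinism** — every draw descends from `SeedSequence(seed,
  spawn_key=...)` per patient/operator/stage; identical config + seed is
  bit-identical.

**What the generator does not emulate:** 3D tumor volumes (a single axial
slice is analyzed by design), PET images (SUV/TLG are scalar draws), ADC
maps (scalars only), direct SUV/ADC–outcome couplings, registration error
between sequences, bias fields, and Rician noise statistics. Passing
tests therefore demonstrate that the pipeline recovers the couplings it
is designed to detect under a controlled imaging model — not that any
particular clinical effect size is reproducible. One visible consequence:
in the generator TLG predicts survival with *low* TLG adverse (TLG
relates to outcome only through its negative coupling to texture),
whereas clinically high TLG is the poor-prognosis direction; the
direction-agnostic cutpoint machinery reports this explicitly.

## Calibration and problem sizes

Null calibration (all couplings zero) is checked at 500 replicates:
Spearman, log-rank and Mann–Whitney type-I error at α = 0.05 fall within
0.05 ± 0.02, and the BH stage's false-discovery proportion under the
global null stays at ≤ 0.1. The log-rank null runs at a raised baseline
hazard (0.08) so that events are plentiful — with ~4 events per cohort
the test statistic is too discrete for a meaningful uniformity check.
Parameter recovery runs at n = 200 with 50–100 replicates (ICC within
±0.05 of a theoretical 0.8; Cox log-HR within ±0.3 of 1.5; the
MPP–TLG rank coupling within ±0.1 of −0.55) and 200 replicates for the
12-patient mutation-count power check (detection ≥ 80%). The end-to-end
run uses the 30-patient default cohort. `scripts/acceptance.py` performs
these computations at the sizes above, chosen to keep a full
reproduction comfortably within a coffee break on one CPU.

## Known limitations

* The texture defaults (σ mapping, 4σ truncation, 64-bin entropy) are
  reconstructions of proprietary software settings; absolute feature
  values are not comparable to that software, though orderings and
  couplings should be.
* Optimized-cutpoint p-values are exploratory; no correction is applied
  across candidate thresholds or across markers, by design.
* The forward-score Cox procedure is a plausible reconstruction of an
  included/excluded-with-score model summary; other stepwise criteria
  would select differently on borderline data.
* Exact Mann–Whitney enumeration is limited to combined n ≤ 12
  (C(12,6) = 924 assignments); beyond that the tie-corrected normal
  approximation is used.
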