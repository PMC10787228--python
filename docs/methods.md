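# Methods

## Forward model and reconstruction

The virtual polarimeter assumes ideal optics: for input state `x` and
analyzer state `y` (both drawn from the six canonical fully polarized states
H, V, P, M, R, L with unit S0), the recorded intensity at a pixel with
Mueller matrix `M` is

    I_xy = gain · a_yᵀ M s_x,      a_y = ½ s_y,

the ½ expressing that an ideal analyzer passes half the intensity of matched
fully polarized light. This is the minimal model under which the standard
36-measurement reconstruction (signed four-term sums per element, first
letter = input, second = analyzer) is exactly invertible: every sum equals
`2·gain·m_ij`, a uniform factor that cancels in m11 normalization. The
printed element/state-pair layout was verified against this model
symbolically and numerically; no index remapping was needed. `element_mueller`
provides ideal rotated-polarizer and quarter-wave-plate matrices so the
generator/analyzer trains can be checked against the canonical states and
non-ideal optics can be injected in sensitivity experiments.

Not modeled: the physical 30° generator–analyzer offset (it only suppresses
specular reflection on the real instrument), wavelength dependence, imaging
PSF, and dark/flat detector corrections.

## Phantom generator

Each phantom measurement image is a ground-truth 16-element Mueller field.
Per element: a per-image mean drawn from Normal(class mean, class
between-image std); plus a spatially correlated texture (Gaussian-filtered
white noise, correlation length 4 px, pointwise sd `texture_sd`); plus white
noise of sd `pixel_noise_sd`. The texture is de-meaned within each image, so
between-image variation is carried entirely by the profile stds and the
per-image average has exactly the stated Normal distribution (up to the
tiny white-noise term) — this makes standard-error-based recovery checks
exact. Class profiles (means ± stds of all 16 normalized elements for
healthy/benign/grade-2/grade-3) are the published cohort statistics; m11 has
mean 1 and std 0 by construction.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| cohort_counts | 35/20/20/20 | the published cohort composition |
| images_per_sample | 6 | 35 healthy samples × 6 = the published 210 healthy images (the per-slide "three to five" acquisitions quoted elsewhere in the source are inconsistent with its own totals; the totals win) |
| height × width | 64 × 64 | large enough that pixel-level noise contributes ≪ the between-image std to an image average; small enough for minute-scale cohort runs |
| texture_correlation_length | 4 px | visible sub-image structure, several independent patches per image |
| texture_sd | 0.01 | comparable to the smaller between-image stds; keeps noiseless 36-state intensities strictly positive for all classes (see below) |
| pixel_noise_sd | 0.005 | detector-scale white noise in the truth field |
| NoiseConfig.read_noise_sd | 0.005 | camera read noise on the intensity scale; shot noise (Poisson, full-well 10⁴) available but off by default |

Physicality. The elementwise clamp |m_ij| ≤ m11 does not guarantee
non-negative probe intensities; the grade-3 class means leave a worst-case
noiseless intensity margin of only ≈ 0.036 across the 36 state pairs, which
noise tails can cross at ~10⁻³ of pixels. Offending pixels therefore have
their polarized part (all elements except m11) shrunk by the largest factor
restoring non-negativity — a projection toward the ideal depolarizer.
Clamping/projection rather than resampling keeps generation deterministic;
the induced bias on cohort element means was measured at ≲ 10⁻⁴ (paired
comparison against the drawn means), far below the ≈ 2×10⁻³ cohort standard
errors. The phantom targets the published statistics, not tissue optics: no
fibers, scatterer-size distributions or wavelength physics.

## MMT parameters

A, b, t, Δ are computed from (m22, m33, m23, m32, m44) of the normalized
matrix. Δ uses a0 = 2, the unique value that reproduces the published
healthy (0.4459) and benign (0.4931) depolarization powers from the
published element averages; a0 is exposed in `MMTConfig` because the formula
leaves it free. Two evaluation modes are provided and tagged in every
result: `from_averages` (formulas applied to the 16-vector of element
averages) and `per_pixel_then_average` (maps computed per pixel, then
averaged). b is linear, so the modes agree exactly; t and A are nonlinear
(Jensen gap), and the per-pixel t dominates t-of-averages.

Known discrepancies, kept deliberately visible rather than patched: the
published per-class t and A values (e.g. healthy t = 0.6418, A = 0.7721)
cannot be obtained from the published element averages via the stated
formulas (direct evaluation gives t ≈ 0.4798, A ≈ 0.7750); the computation
path behind those numbers is unstated. Likewise the published grade-2/3 Δ
(0.549, 0.5944) deviate from the a0 = 2 arithmetic (0.5626, 0.6095). Only
the reproducible subset (b, healthy/benign Δ) is treated as ground truth;
t and A are covered by property checks (t ≥ 0, isotropic-limit zeros,
closed-form points). The claimed t ∈ [0, b] interval is violated by the
published averages themselves (t ≈ 0.48 > b ≈ 0.23); it is logged, not
asserted.

## Statistics

- Percentage difference between group means: `100·|h−c| / max(h,c)`
  (this denominator reproduces all fifteen published healthy-vs-cancer
  values at 1-decimal rounding); both-zero input → 0 by convention.
  Tabulated values use decimal round-half-up.
- Two-group tests: Welch's t by default — the published "paired" comparison
  between 35 and 60 samples is not well-defined; a paired variant exists for
  equal-length inputs and every table labels the test used. Validated
  against a 10⁵-resample permutation oracle and null calibration.
- One-way ANOVA (scipy `f_oneway`) with all pairwise Welch post-hoc tests;
  raw p-values by default, optional Bonferroni. Significance stars use the
  four-band convention * ≤ 0.0332, ** ≤ 0.0021, *** ≤ 0.0002, **** < 0.0001
  (configurable), matching the printed bands.
- Correlation matrix: Pearson over the 15 non-m11 element averages, pooled
  across the supplied samples (per-class on request); columns constant to
  float round-off are reported as missing.
- FDHs: pooled pixel histograms per element and class, 64 bins on [−1, 1]
  (bin count/range configurable; out-of-range pixels are clipped into the
  end bins so counts are conserved). Separability score per element:
  1 − overlap coefficient (sum of bin-wise minima of normalized
  frequencies), averaged over class pairs; ties break on canonical element
  index. Under the default generator the ranking is led by m44 and m32,
  with m31 and m23 next — m31 ranks high because its published stds are
  tiny while its class means are well spread, echoing the source's own
  observation that m31 is also discriminative.

The 8-bit display mapping (v ∈ [−1,1] → round-half-up 255·(v+1)/2) is
display-only; all statistics run on float values, since the ≤ 1/255
quantization error is below the reported stds but there is no reason to
inject it.

## Classification

Nearest-centroid on (m23, m32, m44) — the minimal classifier consistent
with the published monotone orderings (m23, m44: healthy > benign > grade-2
> grade-3; m32 reversed). Per-sample features are the mean element averages
over the sample's images. Distance is Euclidean standardized by per-class
scales (default; handles m32's larger healthy-vs-cancer spread), with a
1e-9 scale floor for degenerate training data; ties break deterministically
in the order healthy < benign < grade2 < grade3. The reference model uses
the built-in profiles as centroids. The published study reports no
classification accuracy; the confusion matrix is a pipeline-level metric of
the synthetic cohort, not a reproduction of a published number.

## Determinism and numerics

A single pipeline seed derives the phantom stream (per sample and image via
`SeedSequence([seed, 977, sample, image])`) and the detector-noise stream
(per acquisition via a CRC32 of the sample id — stable across processes,
unlike Python's string hash). Reruns with the same configuration are
byte-identical, verified by SHA256 checksums over all CSV/JSON artifacts.
Pixels with raw m11 ≤ 1e-9 are masked rather than divided; an all-masked
image is an error. Stacks are float by default so the round-trip oracle is
exact; 16-bit output is a write-time option.

## What passing tests show — and what they do not

The phantom emulates per-class element statistics, spatial texture and
detector noise. It does not model tissue microstructure, instrument
miscalibration, specular artifacts, staining variability, or
element-to-element correlation within a class (elements are drawn
independently; the strong pooled correlations, e.g. m23–m32 ≈ −0.98, are
between-class effects). Recovery and calibration results therefore validate
the pipeline's correctness and statistical behavior on data matching the
published summary statistics — not clinical performance on real slides.

Stochastic checks (cohort-mean recovery within 2 SE, type-I calibration
inside an exact binomial 95% CI, the FDH overlap bound) are two-stage: a
fixed primary seed, and one pre-registered replication seed used only if
the primary fails. The bands exclude ~5% of well-calibrated runs by
construction, so a single fixed seed would fail spuriously at that rate; a
genuine bias fails both stages (joint false-alarm ≈ 0.25%, verified
unbiasedness: recovery z-scores ~ N(0,1) over 20 seeds). Problem sizes in
tests and in the acceptance script are the study defaults (95 samples × 6
images at 64 × 64) except where a check needs many replicates, where 16 × 16
images are used — chosen as the package's own balance of resolution against
replicate count.
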