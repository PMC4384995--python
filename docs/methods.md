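# Methods

This note documents the models, conventions and numerical choices behind
`mulchdeg`, in the order of the pipeline.

## Film degradation from gray values

A buried black polyester film loses opacity as microbes perforate it. The
degradation ratio interpolates the ROI mean gray value linearly between two
calibration references — a fresh film (0 %) and the bare background
(100 %):

    ratio(%) = 100 (ḡ_residual − ḡ_fresh) / (ḡ_background − ḡ_fresh)

*No clamping.* Scanner noise and film curl legitimately produce small
negative ratios in real series (the bundled reference table contains
−4.7 %); out-of-range values are data. The ratio is invariant under any
affine rescaling of the gray axis applied to all three values, so scanner
gain/offset drift cancels as long as one calibration pair is used per
batch.

*ROI placement.* The measurement protocol fixes only the ROI size
(300 × 300 px at 300 dpi ≈ a 2.5 cm square covering the 2 × 2 cm film
piece). The default placement centres the ROI on the centroid of
below-threshold (dark) pixels — deterministic and robust to the film
drifting on the scanner bed — with an explicit row/column override. The
threshold (midpoint of the two calibration grays by default) is used only
for this centroid, never in the ratio itself.

*RGB input* is collapsed by an unweighted channel mean (black film on a
light background is near-achromatic); Rec. 601 luminance weighting is
available. 16-bit rasters are rescaled to the 0–255 range.

*Degradation rate.* The per-week rate over the near-linear early phase is
ambiguous in field practice, so three definitions are exposed and logged:

- `endpoint` (default): week-3 ratio / 3 — the average weekly gain, in
  % week⁻¹;
- `mean3`: plain mean of the week-1..3 ratios (a level, not a slope: on
  data linear through the origin it equals slope × mean week, i.e. 2× the
  slope for weeks 1–3);
- `ols0`: least-squares slope through the origin on weeks 0–3.

Rank-based downstream statistics are insensitive to the choice: on the
bundled tables the isolation-rate correlation is ρ = 0.65 / 0.72 / 0.70
for the three variants.

## Viable counts and isolation rates

CFU per gram of *dry* soil:

    CFU g⁻¹ = colonies / V_plated × dilution × V_suspension / (m_wet (1 − wc))

with water content *wc* defined as water mass per wet mass (oven-dry
convention). Plated volume and counted dilution are required metadata, not
assumed constants. Counting-window rules (30–300 colonies) are not
enforced.

The degrader **isolation rate** is the clear-zone-positive share of
colonies. It is computed from raw colony counts when available and from
the CFU ratio otherwise, with the path recorded — the bundled table
contains one row (YM2) whose printed percentage (51.3) is inconsistent
with its rounded CFU columns (5.1), so both paths are kept and the
conflict is flagged, not resolved. A second internal inconsistency of the
source tables — the published clearing-count range minimum (2.74 × 10³)
vs the smaller value actually present in the table (2.63 × 10³ for soil
HIO) — is likewise surfaced by the reproduce workflow.

## Esterase activity

The assay (100 mg moist soil, 2 mM pNP-valerate in 0.6 ml buffer, 30 min,
30 °C; 75 µl supernatant stopped with 200 µl ethanol + 55 µl 2 M Tris,
A405 read on the 330 µl mixture) gives

    activity = (A_corr / s) × (V_reaction / V_aliquot) / (m_dry × t)

with A_corr = A_sample − A_blank − A_background and *s* the calibration
slope in absorbance per nmol p-nitrophenol in the measured mixture. pNP
absorptivity depends on pH and effective path length, so *s* should come
from the user's own standard series (`fit_calibration_slope`, a
through-origin fit); the packaged default (0.05 A/nmol, from a bundled
*synthetic* calibration series consistent with ε ≈ 1.8 × 10⁴ M⁻¹ cm⁻¹ and
a ~0.9 cm path) is a documented placeholder, not a measured constant.

Activities are reported per gram dry soil (matching the CFU basis; the
basis is recorded in the output). Replicates are summarised by geometric
means; non-positive corrected absorbances are retained in raw output but
excluded from the geometric mean with a logged warning, and summaries of
fewer than three assays warn.

## Trend and correlation statistics

All tie handling uses mid-ranks, uniformly.

**Spearman.** ρ is the Pearson correlation of the rank vectors. The
two-sided p-value is exact (full permutation enumeration) for n ≤ 9 and a
t-approximation (t = ρ√((n−2)/(1−ρ²)), df = n−2) above. At n = 5 the two
differ by up to ~0.08 (the permutation distribution has granularity
1/120); by n ≥ 10 the approximation is adequate for screening use.

**PAVA.** Weighted pool-adjacent-violators isotonic regression is
implemented in-package because the Williams amalgamation is part of the
statistical chain; it is verified against a brute-force search over all
monotone contiguous-block partitions and preserves the weighted grand
mean to 1e-9.

**Williams' test.** Groups ordered by time/dose with a time-0 control.
Pooled within-group variance uses all groups (df = N − k − 1). At
step-down stage *i* the treatment means of groups 1..i are amalgamated
isotonically (weights = group sizes) and the top amalgamated mean is
compared with the control mean:

    t̄_i = (M̂_i − x̄_0) / √(s² (1/n_i + 1/n_0))

Testing starts at the highest group and stops at the first non-rejection,
so rejections are a contiguous suffix of the ordering (asserted on every
run). Default α = 0.025, one-tailed; direction configurable ("increase"
for degrader counts and activities rising from the time-0 control). Zero
pooled variance is degenerate and decided by exact comparison of means.

*Reference values* are not transcribed from printed tables: they are
(1 − α) quantiles of the statistic's null distribution from seeded
Monte-Carlo simulation (50,000 replicates by default, cached per design).
The machinery is pinned by three cross-checks: the one-stage case is an
ordinary one-sided pooled-t comparison whose reference value must equal
the exact Student-t quantile; quantiles reproduce across independent
seeds within MC error; and the realised null rejection rate of the
top-group comparison is α to within Monte-Carlo tolerance.

**Shirley-Williams' test.** Rank analogue: at each stage the control and
the groups still in play are re-ranked jointly, mean ranks are
amalgamated, and the statistic uses the tie-corrected rank variance
N(N+1)/12 · (1 − Σ(t³−t)/(N³−N)). Being rank-based it is invariant to
strictly monotone transformations. Reference values come from the same
Monte-Carlo machinery (ranks of continuous i.i.d. samples are
distribution-free).

**Mann-Whitney U.** Exact two-sided p by enumeration of all C(n₁+n₂, n₁)
labelings for n₁+n₂ ≤ 14 (mid-ranks within the enumeration, so ties are
exact); otherwise a normal approximation with tie and continuity
corrections. The method used is recorded.

**Normality.** One-sample KS against a normal with moments estimated from
the data. Because estimating the moments invalidates the plain KS null
distribution, the default p-value is Lilliefors-corrected
(statsmodels); the plain-KS p is available by flag and labelled. Constant
data is reported as decisively non-normal.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated; all are reproducible byte-for-byte from their seed and emit
ground truth alongside the data.

- **Film scans**: a 320 × 320 px film rectangle (larger than the 300 px
  ROI, so a fresh-film ROI sees film only) in a 400 × 400 image;
  gray_film = 30, gray_background = 200, Gaussian noise SD 2 gray levels.
  Holes are random disks (exponential radius, mean 3 px) plus thin
  rectangular tears (15 % of shapes), with centres sampled from a
  margin-padded region to avoid a hole-poor border; the in-film hole area
  is trimmed to the requested fraction exactly (one-pixel quantisation).
  Residual per-image recovery error of the full pipeline is ≲1.5
  percentage points, dominated by where holes happen to fall relative to
  the ROI.
- **Plates**: Poisson colony counts with mean = suspension concentration
  × plated volume / dilution; clear-zone colonies binomial with the true
  degrader fraction. Cross-soil magnitudes follow the reference design:
  total fungi lognormal around 7 × 10⁴ CFU g⁻¹ (GSD 1.8), degrader
  fractions uniform on 4–45 %.
- **Time course** (weeks 0–4, triplicates): with film buried, the
  degrader density grows logistically (rate 1.5 week⁻¹, carrying capacity
  20× baseline — roughly a 10–20-fold rise over 4 weeks); without film it
  is stationary. Esterase activity is baseline (40 nmol g⁻¹ min⁻¹) plus
  2 × 10⁻³ nmol g⁻¹ min⁻¹ per CFU g⁻¹ of degraders, rendered as
  absorbances by inverting the assay formula with lognormal noise
  (σ = 0.10); counts carry lognormal noise σ = 0.15. The weekly
  degradation ratio follows cumulative degrader exposure (relative to
  carrying capacity, scale 20 % per unit), which saturating growth makes
  near-linear after the first week.
- **Multi-soil datasets**: a Gaussian copula couples the degrader
  fraction and the degradation rate (lognormal, median 1.5 % week⁻¹).
  The latent correlation is calibrated so the *expected sample* Spearman
  at the design's n equals the target, using the exact bivariate-normal
  identity E[r_s] = 6/(π(n+1)) [asin ρ + (n−2) asin(ρ/2)] solved by
  Brent's method — at n = 11 the naive large-n inversion would
  under-recover a 0.63 target by ≈0.045.

What the generators do *not* emulate: spatial soil heterogeneity,
plate-to-plate medium effects, substrate depletion in the assay,
non-monotone community dynamics, and film fragmentation (pieces leaving
the ROI). Passing recovery tests therefore shows the arithmetic and the
statistical calibration are right under the stated noise models, not that
field data will be this well-behaved.

## Problem sizes and tolerances

Defaults chosen for the bundled validation runs: Monte-Carlo reference
values 50,000 replicates; null-calibration checks 10,000 simulated
datasets (binomial SE ≈ 0.0016 at α = 0.025); film recovery 20 replicate
images per fraction; esterase recovery 50 noisy replicates; copula
recovery 1,000–2,000 replicate datasets. PAVA and rank computations are
exact; floating-point assertions use 1e-9 where algebraic identities are
claimed.

## Known limitations

- Williams-type reference values are simulation-based; at extreme α or
  very unbalanced designs the cached 50,000-replicate quantile carries
  ~1 % relative MC error (increase `n_reps` where that matters).
- The exact Mann-Whitney path is O(C(n₁+n₂, n₁)) and capped at
  n₁+n₂ = 14.
- The esterase default calibration slope is a synthetic placeholder;
  quantitative cross-study comparisons require a measured standard curve.
- The reproduce workflow can only recompute aggregates derivable from the
  bundled summary tables; per-figure test outcomes of the reference study
  (raw data unpublished) are covered by the property-based checks on
  synthetic data instead.
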