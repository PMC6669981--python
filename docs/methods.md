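# Methods

This note records the scientific model behind `plantpheno` and the numerical
conventions the implementation commits to. Problem sizes (design layout,
replicate counts, effect sizes) are the package's own defaults and can all be
overridden.

## 1. The experiment being modeled

A facultative parasitic plant is sown, several seedlings per pot, into pots
that either contain one candidate host species or are host-free controls.
Pots are arranged in a randomized complete block design (RCBD): each block
contains every treatment, with more replicate pots for the control (default:
5 blocks × [6 hosts × 3 pots + 9 control pots], 7 plants per pot). Weekly
survivorship is scored per pot; at harvest each survivor is photographed,
weighed and measured. The biological signal of interest is that stronger
hosts kill more parasites and leave survivors that are *paler* (lower
chlorophyll, hence lower green/red ratio) and *plumper* (more mass per unit
height, more compact silhouette).

## 2. Imaging and morphometrics

Photographs show plants on a dark background next to an achromatic white
ruler strip. Segmentation converts RGB to a chosen space (RGB, HSV, HSI or
CMYK), thresholds one channel (Otsu on a 256-bin histogram, or fixed bounds)
and refines the mask by dropping dark pixels and small speckles. Connected
components (8-connected by default, so diagonal stems stay intact) become
ROIs ordered left to right.

Per-ROI measurements:

- **area**: pixel count;
- **bounding-box height**: row extent, converted to mm via the pooled
  ruler scale (pixels per cm, arithmetic mean ± SEM across images);
- **perimeter**: length of the marching-squares contour at the 0.5 level,
  after a Douglas–Peucker simplification pass (tolerance 1 px, capped at
  1/16 of the raw contour length). The simplification is essential: the raw
  marching-squares polygon follows the half-pixel staircase on oblique
  boundaries and overestimates a digitized circle's circumference by ~6%,
  while the simplified contour is within 0.5% for a radius-50 disk and
  within 3% down to radius 6, yet leaves long axis-aligned edges intact
  (a 100-px square measures 398.0). Results are stable for tolerances in
  [0.9, 1.2]; the cap keeps single-pixel components at positive length.
- **perimeter:area ratio** and **circularity** (4πA/P²) as compactness
  ("plumpness") proxies.

Otsu tie-breaking: cuts through runs of empty histogram bins are exact ties
in real arithmetic; the implementation takes the lowest cut within 1e-9
relative tolerance of the maximal between-class variance, so the reported
threshold does not depend on floating-point summation order.

## 3. Color correction and the G/R chlorophyll proxy

Illumination differs between photographs, so ROI color is normalized against
the in-frame white reference before computing the green/red ratio:

1. **Grey-world gains** from the reference region: `g_c = mean(ref) / ref_c`,
   making the reference achromatic while preserving its mean level.
2. **Bradford chromatic adaptation** in XYZ: with cone matrix `B` (Lam/BFD
   constants), `M = B⁻¹ · diag(B·w_dst / B·w_src) · B` maps the (pre-gained)
   reference white exactly onto the destination white (D65 by default).
   The construction is exactly compositional (`M13 = M23 · M12`) and maps
   source white to destination white at machine precision.
3. RGB↔XYZ uses the sRGB/D65 primary matrix. The sRGB transfer function is
   applied on both legs when `linearize=True` (real photographs); for
   linear-light images — including all synthetic scenes — `linearize=False`
   keeps the entire pipeline linear, so correcting the ROI mean equals the
   mean of corrected pixels and the true reflectance ratio is recovered
   exactly under any multiplicative cast.

The corrected mean green divided by corrected mean red (**G/R**) is the
chlorophyll proxy: chlorotic (pale) tissue scores lower.

## 4. Synthetic data with ground truth

`render_scene` draws each plant as a vertical stem plus 2–6 elliptical leaf
lobes; stem and lobe widths scale with a `plumpness` parameter, and
`plant_from_base` trades height for girth along that axis
(height ← base·(1−0.5p)). Pixel color is
`reflectance × illuminant_gains + N(0, σ²)` in linear light, with plant
reflectance `(0.22, 0.22·(1+2·chlorophyll), 0.10)` so the true G/R equals
`1 + 2·chlorophyll`. Ground truth records each silhouette's area, perimeter
(same estimator as the measurement path, so comparisons are
estimator-consistent), bounding-box height (exactly `round(height_cm·ppcm)`
rows by construction) and reflectance ratio. Overlapping silhouettes raise
an error rather than produce ill-defined truth.

`simulate_cohort` generates the RCBD cohort. A single latent *parasitism
intensity* π per host (0 for the control, up to 0.9 for the strongest host)
drives every response:

- weekly survival probability `0.87 − 0.105·π` (≈50% five-week survivorship
  for controls, ≈28% for the strongest hosts), as a Bernoulli chain in which
  dead plants stay dead;
- G/R mean `2.0 − 0.8·π` (SD 0.15);
- lognormal mass `exp(ln 15 + 0.8·π + ε)` (σ = 0.35) and height
  `exp(ln 80 − 0.45·π + ε)` (σ = 0.20), so stronger hosts yield plumper,
  shorter survivors;
- additive block effects (SD 0.05, log scale for mass/height).

Coupling all responses through one latent factor reproduces the qualitative
host ordering and the survivorship–color correlation without tuning any
pairwise covariances. `EffectModel.null()` sets every host equal to the
control for calibration studies. These effect sizes are simulator defaults
chosen a priori to give clearly detectable strong hosts at the default
design; they are not estimates of any particular species' effect.

Realism limits: silhouettes are flat two-tone shapes (no shading, occlusion
or soil clutter), noise is white Gaussian, and the illuminant acts as a
single per-channel gain. These idealizations are deliberate — they make
exact recovery a meaningful test — but mean the generator validates the
pipeline's correctness, not its robustness to field conditions.

## 5. Statistical inference

The experimental unit is the pot. Pot-level phenotype means are computed
over final survivors and weighted by the survivor count, so pots with more
survivors (better-estimated means) carry more weight and empty pots drop
out of the phenotype model while still contributing to survivorship.

The model is `response ~ treatment + block`, fitted by weighted least
squares with cell-means treatment coding and sum-to-zero block coding, so
treatment coefficients are level means averaged over blocks. A
random-block variant (REML via a single variance component) is available
and agrees with the fixed fit on balanced data; residual df is
`n − rank(X)`.

- **Dunnett (many-to-one)**: each host vs the control, adjusted p-values
  from the equicoordinate multivariate t with the contrast correlation
  matrix implied by the actual design and weights. The correlation matrix
  is factored as `R ≈ λλᵀ` (exact for contrasts of independent means that
  share one control; near-exact for weighted RCBD) and the tail probability
  is computed by deterministic Gauss–Hermite × Gauss–Legendre quadrature,
  reproducible to ~1e-8; if the factorization residual exceeds 5e-3 the
  implementation falls back to seeded quasi-Monte-Carlo integration. The
  k = 1 case reduces exactly to the two-sided t-test.
- **Tukey–Kramer (all pairs)**: `p = P(q_{k,df} ≥ √2·|t|)` from the
  studentized-range distribution, with the Kramer SE for unequal
  allocation.
- Adjusted p-values are floored at the unadjusted p, and the family minimum
  (used in FWER studies) is computed from the largest |t| only, which is
  valid because the adjustment is monotone in |t|.

Both procedures were validated against R: estimates, SEs and Tukey adjusted
p-values match `emmeans` to 1e-9 on a frozen reference dataset, and Dunnett
adjusted p-values match `multcomp::glht` within its quasi-Monte-Carlo error
(~1e-4). Simulation calibration on 2000 null cohorts puts both family-wise
error rates within [0.035, 0.065] at α = 0.05.

Auxiliary tests: paired t (two-sided) for matched comparisons and Pearson
r² for the treatment-level survivorship–color relationship.

## 6. Enrichment

For differential-expression summaries, each (tissue, GO-slim term) 2×2 table
of up/down counts is tested with the two-sided Fisher exact test using the
point-probability rule (the convention of R's `fisher.test`): the p-value
sums hypergeometric probabilities of all tables, at fixed margins, no more
likely than the observed one. Zero-margin tables are uninformative and
return p = 1 with a warning. Significance is a per-term α cut by default;
Benjamini–Hochberg across terms is available as an option.

## 7. Determinism

All randomness flows through explicitly seeded `numpy` generators;
simulation studies derive per-replicate seeds from a `SeedSequence`. CSV and
JSON writers fix column order, line endings and rounding, and PNG output is
8-bit (which limits image-derived color to ~1% quantization accuracy —
tabular phenotypes are unaffected). A full CLI pipeline run is
byte-identical across invocations with the same seed.
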