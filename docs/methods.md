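# Methods

This note documents the models, parameter choices, and numerical decisions
behind `fvmap`, and states what the synthetic generator does and does not
emulate.

## Contact-mechanics model

Force on a sharp four-sided pyramidal tip indenting an elastic half-space:

    F = C · E · δ²,      C = tan(α) / (√2 · (1 − ν²))

with `F` the force, `E` Young's modulus, `δ` the indentation depth, `α` the
tip face half-angle, and `ν` the Poisson ratio (0.5, incompressible). A
conical alternative `C = 2·tan(α) / (π·(1 − ν²))` is selectable via
`CantileverSpec.tip_geometry`. With `E = 10 kPa`, `ν = 0.5`, `α = 17°` and
`δ = 500 nm`, the model gives `F ≈ 0.72 nN`.

Units are chosen so no large exponents appear in the arithmetic: piezo
positions and indentation in nm, forces in nN, spring constant in N/m (which
is numerically identical to nN/nm), moduli in Pa. The least-squares slope
`β` of `F` against `δ²` is in nN/nm²; the conversion to Pa is
`E = β · 10⁹ / C`.

## Indentation depth

The piezo extension `z` moves both the sample and the cantilever base; the
cantilever deflects by `(F − b)/k` where `b` is the pre-contact force
baseline and `k` the spring constant. The indentation past the contact point
`z_c` is

    δ_i = (z_i − z_c) − (F_i − b)/k.

## Contact-point detection

The contact point is found by exhaustive piecewise least squares: for every
candidate index `c`, model the curve as a constant baseline before `c` and
`F = b + β·δ(c)²` after `c`, and pick the `c` minimizing the total squared
error (ties resolve to the lowest index). The scan is O(n), not O(n²): for
fixed `b` (the pre-candidate mean, itself updated by prefix sums), the
post-contact slope profiles out as `β = S_Fδ²/S_δ⁴` (clamped at 0), and all
the needed sums — of `F`, `F²`, `u`, `u²`, `u³`, `u⁴`, `Fu`, `Fu²` with
`u = z − F/k` — are maintained incrementally as the candidate advances.
Inside the scan `δ` is left unclamped for pre-contact samples; this keeps
the objective a smooth function of the candidate index and does not bias the
minimum, because the true contact point makes the pre-contact branch flat.

Fit quality control (defaults in `FitOptions`): at least 8 baseline and 8
contact samples, `r² ≥ 0.80` on the contact branch, fitted modulus within
[50 Pa, 1 MPa]. A warning (not a rejection) flags fitted contact radii
outside 20–1000 nm, where the sharp-tip half-space model is dubious.

## Map segmentation

Valid pixels are quantized into 256 levels between the 1st and 99th
percentiles (values outside are clipped into the end bins). Otsu's threshold
maximizes the between-class variance

    σ_b²(t) = ω₀·ω₁·(μ₀ − μ₁)²

by exhaustive search; the argmax comparison is carried out in exact integer
arithmetic on the histogram counts (cross-multiplied rationals), so the
result never depends on floating-point rounding, and ties resolve to the
lowest level. Above-threshold pixels are labeled glial (stiff), the rest
axon (soft); since quantization is monotone in modulus, the glial class
always has the higher mean, matching its anatomical definition.

## Typical modulus

Per eye and class, the "typical" modulus is the mode of a Gaussian kernel
density estimate (Silverman bandwidth) evaluated on a 512-point grid and
refined by bounded scalar minimization. The mode is preferred over the mean
because modulus distributions are right-skewed; a warning is emitted when a
secondary KDE peak reaches 95 % of the main one (multimodal distribution,
mode ill-defined). Classes with fewer than 50 valid pixels are refused
(`InsufficientPixelsError`) rather than summarized unreliably. Alternatives
(`gaussian_fit`, `histogram_max`) are available for sensitivity checks.

Known bias: Silverman's rule oversmooths skewed densities, displacing the
estimated mode a few percent toward the mean (≈5 % for a lognormal with
shape 0.3 at n = 10⁴). This is inherent to the estimator, not a bug.

## Group statistics

- One-way ANOVA from explicit sums of squares; groups with zero total
  variance raise `ZeroVarianceError` instead of returning an infinite F.
- Fisher-LSD post-hoc pairs using the pooled within-group MSE, uncorrected
  by design (it is protected by the preceding ANOVA).
- Spearman rank correlation via midranks with the t-approximation
  (delegated to `scipy.stats.spearmanr`).
- Percent decrease of group means relative to week 0.

All hand-written statistics are verified against brute-force oracles and
scipy to 10⁻¹⁰ in the test suite, and the ANOVA's type-I error under the
null is empirically calibrated to 0.05 ± 0.02.

## Synthetic generator

**Phantom**: a 20 × 20 µm² region at 128 × 128 pixels (156.25 nm pitch).
Soft elliptical inclusions (axon bundles, diameters 0.2–2 µm) are placed by
rejection sampling until the soft area fraction reaches the target (default
0.4 ± 20 % relative). Pixel moduli are lognormal around the phase means
(defaults 15 kPa glial / 5 kPa axon, CV 0.2), parameterized so the
arithmetic mean equals the phase mean exactly.

**Force curves**: the noiseless force solves `F = C·E·((z − z_c) − F/k)²`
for the physical root using the numerically stable quadratic form
`2c/(b + √(b² − 4ac))`. The contact point is snapped onto the piezo sample
grid so that noiseless curves round-trip through the fitting pipeline
exactly. Gaussian force noise (default 0.05 nN, i.e. 2 % of the trigger) is
added; the ramp extends a 10 % margin past the depth at which the 2.5 nN
trigger force is reached, and the curve is truncated at the first trigger
crossing, as an instrument would.

**Study design**: the default longitudinal design has a week-0 group of 10
eyes and week-4/8/12 groups of 6, each experimental eye paired with an
untreated contralateral eye, plus a 6-eye drug-vehicle control arm at week
0. Group stiffness declines are built in as relative multipliers (glial
1 / 0.645 / 0.258 / 0.194; axon 1 / 0.544 / 0.291 / 0.241 at weeks
0/4/8/12); between-eye biological variability is lognormal with CV 0.15;
contralateral eyes always draw from the week-0 (multiplier 1) distribution.
An accompanying intraocular-pressure generator produces mean-reverting
time courses around 35 mmHg (elevated) or 12 mmHg (normal) with
re-elevation events when pressure decays below 30 mmHg.

**What is not emulated**: cantilever calibration error, hydrodynamic drag
and viscoelastic rate dependence, tip blunting and contamination, finite
sample thickness (substrate stiffening), adhesion and snap-to-contact,
piezo hysteresis/creep, spatial drift between pixels, and instrument 1/f
noise. Force noise is white Gaussian; real deflection noise is colored.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.Generator` seeded explicitly;
  study-level generators spawn child seeds below 2³¹.
- The staged pipeline stamps every artifact with a SHA-256 hash (16 hex
  chars) of the resolved configuration and refuses to resume into a
  directory produced by a different configuration. Identical config + seed
  gives byte-identical study tables and reports.
- CSV tables are written with `%.9g` floats, enough to round-trip float32
  map data and keep rewrites byte-identical.
- Validation helpers (`fvmap.validation`) run reduced problem sizes (32 × 32
  rasters, 128 samples per curve) for the 20-replicate longitudinal checks
  so the whole validation completes in minutes on one CPU; the defaults of
  the library itself are the full 128 × 128 / 200-sample settings.

## Limitations

- The quadratic contact model assumes a sharp indenter; at indentations
  comparable to the 20 nm tip radius the true response is Hertzian
  (`F ∝ δ^1.5`), so very stiff samples fitted at small depths are biased.
- Otsu segmentation assumes a bimodal histogram; when the phase-mean ratio
  approaches the within-phase spread, the threshold degrades gracefully but
  the class masks lose meaning (explored in the separability-limit test).
- Fisher LSD makes no multiplicity correction beyond ANOVA protection.
- The KDE mode inherits Silverman smoothing bias (see above).
- ANOVA on per-eye typical moduli ignores the (small) uncertainty of each
  typical-modulus estimate.
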