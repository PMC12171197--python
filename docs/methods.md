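# Methods

This note records the models, conventions and numerical choices behind
`leafwater`, in the order data flows through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Gravimetric water content

Water content is the water fraction of fresh mass, `M = (G − G₀)/G`, with
`G` the current mass and `G₀` the oven-dry mass. The API works in
fractions throughout; percentages are display-only. The inverse
`G = G₀/(1 − M)` is exact and is property-tested as a round trip.

## Synthetic spectral model

The generator emulates what the estimation method assumes about NIR leaf
reflectance, not leaf optics per se:

```
R(λ; M) = base(λ) − M · [d_broad + Σ_k d_k · exp(−(λ − μ_k)² / 2σ_k²)]
```

then per-spectrum scatter `(1 + ε_m)·R + ε_a` and i.i.d. band noise, all
clipped at zero. Defaults: 224 bands uniform on 900–1700 nm (the nominal
grid of a line-scan NIR imager; all code takes the grid as data and never
assumes uniformity), absorption centres {1440, 1190} nm with widths
{80, 55} nm and depths {0.55, 0.28} per unit water content plus a
broadband depth of 0.12, scatter σ_m = 0.05 and σ_a = 0.02, water content
uniform on [0.14, 0.77] (the observed range of drying peach leaves).

Two noise scales exist because two kinds of spectra exist: a *sample*
spectrum is the mean over a leaf region of thousands of pixels, so its
band noise is small (default 5×10⁻⁴); a *cube pixel* carries full detector
noise (default 5×10⁻³). The distinction matters for NISDI, whose slope
term differentiates adjacent bands and therefore amplifies band noise by
`1.3×10³·√2/Δλ`.

What the generator does **not** emulate: wavelength-dependent scatter,
instrument drift, specular glint, leaf-structure covariates (cuticle
thickness, palisade layering) and water-band shape changes with bound vs
free water. Passing tests therefore demonstrate correctness of the
*method* under the stated statistical structure, not field performance.

Drying series decay the water mass geometrically (factor 0.55/step over 4
steps); the oven protocol is not modelled physically. Synthetic cubes
place an elliptical leaf on a dark flat background (reflectance ≈ 0.06),
with a midrib-plus-branches vein mask whose true water content exceeds the
lamina by a configurable offset (default 0.1, clipped at 1 with a
warning); the lamina also carries a mild ±0.03 tip-to-base gradient so the
map is not piecewise constant.

`planted_nisdi_table` supports parameter-recovery tests: it replaces the
water content with `affine(NISDI) + ε`, scaling `var(ε)` to a requested
signal fraction (default 0.96), so the expected prediction R² is known by
construction.

## Cubes, calibration, segmentation

ENVI I/O supports BIL/BIP/BSQ interleaves and integer/float data types
2/3/4/5/12; round trips are bit-exact for the written dtype. White and
dark frames may be single scan lines broadcast along the scan axis
(push-broom convention). Calibration is elementwise
`R = (I − B)/(W − B)`; any non-positive denominator at a used entry is an
error listing offending indices, since it means the reference frames are
invalid there.

Segmentation replaces the original workflow's proprietary SVM step with a
transparent equivalent, because the choice is instrumental: with labelled
pixels, a logistic-regression pixel classifier; without, an Otsu threshold
on the ratio of a bright band (1070 nm) to the water band (1440 nm), each
averaged over a ±50 nm window to suppress single-band noise on dark
pixels. The ratio is invariant to band-wise constant rescaling. Otsu
always splits, so the split is accepted only if the upper class exceeds
the lower by >15% in mean ratio — a scale-invariant leaf-likeness check;
otherwise an empty mask and a warning are returned. Masks are stored as
PNG. Pixel coordinates are 0-based row-major.

## Preprocessing

- **SNV**: per-row centring and scaling, `n−1` standard deviation
  (pinned by tests). Constant rows are errors.
- **MSC**: per-row least squares `x ≈ a + b·ref`, returning `(x − a)/b`.
  The reference defaults to the column mean; pipelines freeze the
  calibration-set mean and reuse it for held-out sets to avoid leakage.
- **SG**: Savitzky–Golay, default window 11 / polyorder 2 (the source
  workflow names the filter but not its parameters; these are common
  chemometric defaults). Edges use the polynomial of the outermost full
  window, so every band stays defined for index extraction. Derivatives
  are per-nm, using the mean grid spacing.
- **Nor**: per-row min–max to [0, 1] (the cited normalisation is
  undefined in the source; min–max is the simplest row normalisation).
- **FD**: `np.gradient` against the wavelength grid — central differences
  inside, one-sided at the ends, units nm⁻¹.

The comparison harness applies each of the nine treatments (plus raw),
selects the PLSR component count in 1..10 by minimum 10-fold RMSECV, and
ranks by RMSECV. Fold assignment depends only on (n, k, seed). Component
counts are re-selected per dataset, never hard-coded.

## Vegetation indices

The slope spectrum `D` is the central difference
`(R_{k+1} − R_{k−1})/(λ_{k+1} − λ_{k−1})` (one-sided at the ends), in
nm⁻¹: the defining phrase "rate of change between adjacent wavelengths"
leaves the stencil open, and the 1.3×10³ coefficient is only dimensionally
sensible for per-nm slopes, so central-per-nm is implemented and
documented. `NISDI = 1.3×10³·D₁₅₅₉ − 1.9·R₁₄₃₉`; the anchors snap to the
nearest grid band (real instrument grids do not contain those integers)
and out-of-span grids are errors naming the missing anchor. NISDI is
linear in the spectrum — tested, and the basis for the map-averaging
identity below. It is counted as a 3-wavelength model (two bands for the
slope, one for the reflectance).

Pair searches evaluate all ordered pairs (both triangles, since reported
optima are ordered), correlate against water content, and return the full
|r| heatmap plus the argmax with ties broken by (lower i, lower j).
Undefined index values (zero denominators in RVI/NDVI) are dropped
pairwise with a logged count. Pearson p-values come from the exact
`t = r√((n−2)/(1−r²))` two-tailed test. Univariate index models are OLS
with an intercept (whether the original index model had one is unstated;
including it is the conservative choice).

## Wavelength selection

- **CARS**: 50 Monte-Carlo iterations, 80% sample subsets, PLS
  coefficients ranked by magnitude. The retained-count schedule is the
  two-point exponential fit (all p bands at iteration 1, 2 at iteration
  N); at each iteration exactly the scheduled number of bands survives,
  drawn *without* replacement with probability proportional to
  |coefficient| — the schedule fixes how many, competitive reweighted
  sampling decides which. Each iteration's subset is scored by 10-fold
  RMSECV on the full sample; the minimum wins. When fewer bands survive
  than PLS components, the count is clamped with a warning.
- **SPA**: projection chains from every start band (each step adds the
  band with maximal norm in the orthogonal complement of the chosen
  ones), capped at 30 variables; rank-deficient chains truncate with a
  warning. Candidate (start, size) sets are scored by MLR RMSE on a
  seeded 2/3–1/3 split (the source pairs SPA with an RMSE criterion but
  names no model; MLR is SPA's traditional companion).
- **UVE**: p noise bands at amplitude 10⁻¹⁰ are appended (stability is
  scale-free, so the amplitude only guards the PLS numerics);
  coefficient stability `c = mean/sd` is estimated by leave-one-out when
  n ≤ 200, else 100 Monte-Carlo leave-10%-out rounds. Real bands must
  exceed `cutoff_factor × max|c_noise|`; survivors are ordered by |c| and
  truncated at the count minimising 10-fold RMSECV.

All selectors are deterministic under their seeds. PLS component counts
inside selectors are chosen by inner 10-fold CV, capped at 10, using
nested coefficient paths (one PLS fit yields every sub-model's
coefficients), which keeps the inner CV to one fit per fold.

## Regression and metrics

Splitting is random 70/30 under a seed (the original split procedure is
unstated), with a stratified-by-wc-quantile option. Back-ends: PLSR with
7 components (clamped to min(n−1, p)) for characteristic-wavelength
models — the preprocessing harness re-selects by CV instead; MLR by least
squares with an explicit collinearity check that names the offending
column; RF with 100 trees and seed 42; ANN with 4 ReLU hidden layers
(widths 64/32/16/8 — the layer count is specified upstream, the widths
are this package's choice), inputs standardised, exactly 1000 optimiser
iterations (convergence-based early stopping disabled).

MLR has a documented `min_norm` escape hatch: row-normalised spectra make
full-band designs *exactly* singular (SNV forces zero row means; SG edge
bands lie on a single polynomial), so the pipeline's model grid fits the
minimum-norm least-squares solution there, as chemometrics packages
effectively do via pseudo-inverses. The strict error remains the API
default.

Metrics: `R² = 1 − SS_res/SS_tot` with SS_tot about the evaluation set's
own mean (including prediction sets — the most common R²ₚ convention, made
explicit because it is often left undefined); RMSE is the root mean
squared residual. Cross-validation pools out-of-fold predictions before
computing RMSECV/R²_cv.

## Ranking, maps, cross-species

The ranking rule encodes the parsimony argument used to prefer a
3-wavelength index model over a 12-wavelength ensemble: among models
within ΔR²ₚ ≤ 0.025 of the best, take the fewest wavelengths, break ties
by lower RMSEP. The packaged reference table of published model metrics
(`leafwater/data/reference_model_metrics.csv`, from the orchard drying
study the generator emulates) is used only to verify that the rule
reproduces that known decision; the published CARS/SPA/UVE wavelength
lists ship as a reference fixture only and constrain nothing.

Water maps apply a frozen model per leaf pixel. Predictions are stored
unclipped with a count of out-of-range pixels; rendering clips to the
display range (default [0, 1]), maps low→blue / high→red through a
standard colormap (cosmetic, configurable) over a neutral background, and
writes deterministic bytes (colors computed directly, no plot canvas),
plus a gradient-strip colorbar and a JSON scale sidecar. For models
linear in reflectance, the masked mean of the map equals the prediction
on the masked mean spectrum exactly; for RF/ANN it need not, and tests
assert the identity only for linear models.

Cross-species evaluation applies the frozen model without refitting,
resampling external spectra to the model grid by linear interpolation
when grids differ (an error if the external grid does not span the
model's anchors), and reports Pearson r/p, R²ₚ and RMSEP overall and per
subgroup. The default study simulates a matched-model "apple" table
(same spectral model, shifted wc range) and a shifted "lettuce" table
(shallower troughs, stronger scatter, high wc range) to exercise the
near-transfer vs cross-growth-form contrast; the latter's R²ₚ can go
negative because the frozen calibration is biased under the shifted
generator — the harness reports it as computed.

## Pipeline determinism and problem sizes

`run` fans one seed out through `numpy.random.SeedSequence` into
per-stage seeds; reports serialise with sorted keys and contain no
timestamps or paths, so repeated runs are byte-identical. Default study
size is 400 samples × 224 bands with a 48×48 map cube and 133-sample
external tables — chosen so the calibration split (280) exceeds the band
count (a full-spectrum MLR needs that) while the full grid of
3 selectors × 4 regressors + 4 full-spectrum + 4 index models (20 rows)
completes in well under a minute per stage on one CPU. Tests use 60–100
band grids where the full 224 adds nothing.

## Known limitations

- The generator's low-rank spectral structure makes two-band ratio
  indices nearly ideal, so the synthetic study's winner is typically a
  pair-index model rather than NISDI; the ranking rule, not the winner's
  identity, is the tested contract.
- SPA's advantage (collinearity avoidance) barely shows on white-noise
  nuisance designs; its planted-recovery test uses an orthogonal-basis
  construction instead.
- Segmentation assumes a dark, spectrally flat background; cluttered
  backgrounds need the supervised path.
- No radiative-transfer modelling, no canopy/satellite indices, no GPU
  training.
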