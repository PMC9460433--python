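# Methods

This note documents the models, conventions and numerical choices behind
`uavfvc`, in the order the pipeline runs them, and states what the bundled
synthetic data can and cannot show.

## Synthetic scene model

The generator emulates a plateau tailings site imaged by a low-altitude RGB
survey. It is the package's test substrate, not a photogrammetric simulation:
there is no camera model, no dense-matching step, and no atmosphere; the
orthomosaic and the cloud are produced directly.

**Class geometry.** A Gaussian white-noise field is smoothed with an isotropic
Gaussian kernel (correlation length 2 m ≙ 25 pixels at the default 0.08
m/pixel) and cut at the quantiles of the requested areal fractions. This
gives spatially coherent, smooth-boundaried blobs — the structure an
object-based analysis presumes — and hits requested fractions essentially
exactly (tested at ±2 percentage points). Classes sit in a fixed order along
the field (water in the lowest blobs, then vegetation, bare land, tailing
sand), so vegetation/bare-land mixing zones exist by construction. Default
fractions: vegetation 0.36, bare land 0.34, tailing sand 0.22, water 0.08.

**Terrain.** Elevation is a terraced ramp (7 treads by default) normalized to
span exactly the configured relief (140 m), with gently sloped treads and a
1% cross-slope so no derivative is identically zero. Slope is computed in
degrees from `numpy.gradient` (central differences inside, one-sided at
borders) with the pixel size as spacing.

**Spectral model.** Per class, RGB is drawn from a trivariate normal whose
covariance is a rank-one "brightness" term (common to all three channels —
it cancels in every ratio index and stands in for illumination/texture)
plus independent chromatic noise per channel, then 2 DN of sensor noise,
rounding, and clipping to [0, 255]. The means and noise scales are a
*forward calibration*: they were chosen once so that the per-class means and
spreads of the visible indices computed downstream land near values reported
for real tailings scenes — vegetation weakly green (VDVI ≈ 0.03, broad),
bare land bright and reddish (VDVI ≈ 0.04, tight), tailing sand bright gray
(VDVI ≈ 0.02, very tight), water dark blue (VDVI ≈ −0.25). Dark-blue water
is the physically expected signature (B ≫ G) and is what makes the scene
histogram of a usable index bimodal; it is a deliberate choice of realism
over one printed table row that reports water with a slightly positive VDVI.

**Point cloud.** The count is Poisson with mean footprint-area × density
(default 214.36 points/m²); planimetric positions are uniform over the
footprint; each point copies the RGB of its containing pixel (tested
exactly); z is bilinear in the elevation grid at pixel centers. Real dense
image-matching clouds have spatially correlated density, occlusion holes and
color bleeding at boundaries; none of that is modeled, so the mapping stage
here sees a best-case cloud and Q = 100% is the expected outcome at these
densities.

**Coordinates.** All rasters are north-up with pixel-center world
coordinates; y decreases with row. Files are plain TIFF with the
geotransform in a JSON ImageDescription tag, clouds are CSV (x,y,z,r,g,b),
polygons GeoJSON — everything stays readable without GIS tooling.

## Visible-band indices and index selection

All nine formulas operate on real-valued bands; the lowercase r, g, b used by
ExG and CIVE are chromaticity-normalized (r = R/(R+G+B)). Where a
denominator vanishes the output is NaN, never 0 — zero is a meaningful index
value. On exact arithmetic every finite value of every index provably lies
inside its theoretical range for valid 8-bit input (property-tested, and
swept over 10⁶ random pixels), so the out-of-range elimination step of the
selection procedure can only fire on data whose values were produced by
external raster arithmetic (where such violations are occasionally observed
in practice); it is retained for that case and audited in the report.

Bimodality is judged on a 256-bin histogram over the theoretical range,
smoothed with a 5-bin moving average. A mode counts if its prominence is at
least 5% of the tallest smoothed count; modes closer than 10% of the
histogram span merge (tallest survives); exactly two surviving modes means
bimodal. These thresholds are declared defaults — the qualitative criterion
("obvious double peaks") fixes no numbers — and they are deliberately
interpreted against the *theoretical* span: an index like CIVE, whose
dynamic range occupies a sliver of its wide [17, 20] interval, does not get
credit for micro-structure inside that sliver.

Survivors are ranked by the mean of their per-class (population) standard
deviations. On the default scene VDVI wins this ranking for a structural
reason: among the [−1, 1] indices it is the least noise-amplifying — a
first-order expansion around gray gives sensitivity ≈ 0.25·(δ_R + δ_B)
against ≥ 0.33 for ExG and ≈ 0.5–1.0 for the difference/squared-band
indices — while CIVE and EGRBDI, the only lower-noise alternatives, fail
the bimodality screen. The audit trail records every elimination reason.

## Segmentation

The fusion cost is the *increase* in weighted heterogeneity a merge would
cause (the color part is a pooled-variance difference and is provably ≥ 0;
this is the standard form — a merge-independent sum would not drive any
merging). Conventions the criterion needs but no reference fully fixes:

- perimeter l = exposed unit pixel edges; b = shorter side of the
  axis-aligned bounding box; σ_c = population standard deviation;
- compactness uses l·√n (area-weighted l/√n), smoothness area-weighted l/b;
- admission threshold: cost < scale² (squared-scale convention);
- default weights w_color 0.7 / w_shape 0.3 (spectral factor deliberately
  above shape), smoothness 0.4 / compactness 0.6; layer weights default to 1
  each and are not normalized, so adding a terrain layer genuinely adds cost
  across its breaks;
- merging is by rounds of *local mutual best fitting*: every segment names
  its cheapest neighbor (ties to the lowest segment id, ids being the
  smallest original pixel index in the segment, row-major), and all mutually
  best admissible pairs merge simultaneously. The minimal-cost edge is
  always mutual, so the procedure cannot stall while admissible merges
  remain, and the fixed tie-break makes it deterministic.

Note the *shape* part of the cost can be negative (merging two bars into a
square reduces l/b heterogeneity); the total cost is left unclamped, which
simply means shape-improving merges are favored. The engine is vectorized
over the region-adjacency graph but is tested for exact partition equality
against a from-scratch, plain-Python greedy re-implementation on hundreds of
random small images.

LV(L) is the mean per-segment population std of the spectral layers at scale
L, averaged over layers; ROC(L) = (LV(L) − LV(L₋₁))/LV(L₋₁) × 100, undefined
at the first scale and wherever LV(L₋₁) = 0 (skipped with a warning). The
optimal scale is the global ROC peak. The default candidate grid is 10 to
100 in steps of 10: the step follows the reference procedure, and the stop is
sized to the bundled scenes, whose characteristic object scale (blob size ~25
px) is reached by scale ≈ 20; a flat profile raises with diagnostics rather
than inventing a peak.

## Random forest and accuracy

Each of the K trees (default 75) grows on an n-draw bootstrap; at every node
⌈max_features · n_features⌉ (default 0.1, floor 1) randomly chosen features
are scanned over midpoint thresholds for minimal weighted Gini; growth stops
at depth 16, below 3 samples, at purity, or when nothing varies. Defaults
are the published grid-search optimum for this task. All tie-breaks are
fixed (lower feature index, lower threshold, first class in canonical order
for leaf majorities and vote ties) and per-tree RNG streams are derived from
the master seed at fixed offsets, so a seed fully determines the model.
Prediction is a strict majority vote; vote counts per row always sum to K.

The confusion matrix is stored with rows = classified, columns = reference;
PA divides the diagonal by column totals, UA by row totals. Kappa uses the
product form, kappa = (N·Σa_ii − Σ a_ti·a_it)/(N² − Σ a_ti·a_it): the
additive variant sometimes printed alongside it is inconsistent with the
values it is printed next to, while the product form reproduces them (the
package's metrics are also cross-checked against scikit-learn). PA of a
class absent from the reference is reported as NaN, not 0.

Pipeline features per segment: three band means, three band stds, mean of
the chosen index, mean elevation, mean slope, area (10 features — so each
node sees 1 random feature under the defaults, which keeps the 75 trees
decorrelated). Reference labels for training and evaluation are the
majority truth class per segment; the split is stratified per class, 60%
train, singletons going to train.

## Mapping and FVC

With orthomosaic and cloud in one georeferenced frame the general
image-to-cloud transformation collapses to a vertical projection, so
mapping is point-in-polygon on (x, y) with boundaries counting as inside
(deterministic and conservative for cover). A polygon counts as mapped when
it contains at least one point. The automatic purge applies Otsu's threshold
to the per-point VDVI *only* when that distribution is bimodal; a unimodal
distribution is taken as already clean. A raw Otsu split would bisect any
clean unimodal vegetation population and roughly halve the cover estimate —
the guard is what makes an automated stand-in for a manual, judgment-based
cleanup defensible. An explicit threshold bypasses the guard. FVC is
reported in percent at two decimals.

## Problem sizes and limitations

Default end-to-end runs use a 256×256-pixel scene (~90,000 cloud points) and
a 10-scale LV-ROC sweep — about 15 s on one CPU — which is the size at which
all statistical checks in the test suite are run. Numbers measured on
synthetic scenes (OA ≈ 0.99, Q = 100%, FVC within a fraction of a point of
truth) characterize the pipeline's internal consistency under the generator's
assumptions — spatially coherent classes, Gaussian spectra, a hole-free
uniformly sampled cloud — and are not accuracy claims for real imagery, where
mixed pixels, shadows, registration error and cloud artifacts all degrade
every stage. The segmentation cost is O(edges) per merge round and the
engine comfortably handles 10⁵–10⁶-pixel rasters; orthomosaics of 10⁸ pixels
would need tiling, which is out of scope. The point-cloud format is plain
CSV; LAS input was deliberately not implemented to keep the artifact free of
binary formats.
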