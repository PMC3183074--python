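# Methods

## Scope and data model

The package analyzes longitudinal single-animal records: each animal has an
identity, a dataset/trial label, a set of observation ages (days post slide
preparation), an estimated lifespan, and one timecourse per biomarker.
Lifespan is estimated as the midpoint of the interval between the last
observation at which the animal responded to stimulation and the first at
which it did not — the expectation under a uniform prior on the time of
death within the sampling interval. Animals never observed dead are
right-censored: retained in the records, excluded from all regressions.
Flagged animals (e.g. individuals that reproduced and could not be
distinguished from offspring) are likewise dropped before statistics, with
counts recoverable from the records.

## Synthetic cohorts

The generator is the package's test substrate and defines the conditions
under which all self-contained claims are evaluated.

**Lifespans** are drawn from a Gaussian truncated below at `window end +
sample interval` (day 8 under the default day-3–7 window with daily
sampling), so every simulated animal survives the full measurement window —
mirroring the premise that under 3% of a real cohort dies before day 7. Only
second-moment structure matters for the R² targets, so the real
distribution's mild skew is not modeled. Plain truncation of N(10.7, 1.9²)
at 8 would raise the post-truncation mean by ~0.3 d, so the underlying
(μ, σ) are calibrated numerically (truncated-normal moment equations solved
with `fsolve`) so that the *achieved* post-truncation mean and SD equal the
requested values. The calibrated Gaussian has substantial mass below the
cutoff; the generator warns and reports achieved moments whenever the
removed mass exceeds 5%.

**Biomarkers** follow the simplest model achieving an exact planted R²: the
true day-window slope of biomarker *m* for animal *i* is
`s_i = a + b·L_i + ε_i` with `b = sign·sqrt(R²)·slope_scale / lifespan_sd`
and `ε ~ N(0, slope_scale·sqrt(1−R²))`, so `Var(b·L)/Var(s) = R²` exactly.
Daily values are the line through (window midpoint, baseline) with slope
`s_i`, plus iid N(0, noise_sd²) measurement jitter added **per day**, so the
window-summary least-squares slope is itself an estimate and that code path
is exercised. Defaults: baseline 10, slope SD 1 across animals, noise_sd
0.3 — with five in-window days the slope-estimation variance is
0.3²/10 ≈ 0.009, attenuating recovered R² by under 1%, i.e. negligible
against the ±0.05 recovery tolerance. The default "paper-like" panel plants
slope R² values of 0.27 (+, length), 0.27 (−, autofluorescence), 0.20 (+,
motion), 0.26 (−, texture), 0.30 (+), 0.20 (+) and 0.10 (−) for the three
reporters. Signal is planted in slopes only; window means are uninformative
by construction, which is why mean-term weights vanish in simulated
survival-index fits.

**Images.** The procedural worm is a cubic-spline centerline (~300 px arc)
with a tapered half-width profile (zero at the tips, ~9 px mid-body) on a
120×480 canvas — small enough for seconds-scale tests. Brightfield: dark
body (0.35) on bright background (0.85) with a *fixed per-animal* smoothed
speckle field scaled by `texture_roughness` (which grows linearly with
simulated age) plus per-frame camera noise (σ 0.01); the speckle travels
rigidly with the body so inter-frame change reflects motion, not texture
resampling. Fluorescence: hotspot Gaussians anchored at normalized arc
positions (head 0.08, vulva at `vulva_position`, tail 0.92; "body" instead
raises the whole-body level) over a dim in-mask background, plus camera
noise. Sequential frames are rigidly displaced by `motion_displacement`
pixels. Ground truth (mask, centerline, arc length, vulva pixel, hotspot
centers) is emitted alongside the frames. What the generator deliberately
does **not** emulate: anatomy, death/decomposition appearance, focus drift,
illumination artifacts, and occlusion — so passing tests demonstrate
algorithmic correctness against known geometry, not robustness to real
microscopy pathology.

## Image analysis

*Pixel classifier.* The in-animal probability model is logistic regression
(unpenalized maximum likelihood) over five per-patch statistics — mean, SD,
min, max, center value — at patch radius 4. The feature set is a design
choice; it is small and sufficient at synthetic contrast. Masking keeps the
largest above-threshold (0.5) connected component and fills holes; an empty
result raises a "no animal found" signal.

*Centerline.* Cost inside the mask is `(max(DT~) − DT~) + 10⁻³` per visited
pixel, where DT~ is the Euclidean distance transform after a σ=1 Gaussian
smoothing: the smoothing breaks exact ties on chamfer plateaus that
otherwise let the minimum-cost path wander within flat-cost bands, and the
small constant adds a mild shortness bias. The least-cost 8-connected path
between head/tail seeds (user-supplied, or the two mask pixels at maximal
geodesic distance) is found with `skimage.graph.MCP` (node-cost-sum
semantics, verified against a brute-force Dijkstra oracle), lightly smoothed
(5-sample moving average, endpoints pinned) to counteract the staircase
inflation of 8-connected paths, and resampled at 1-px arc spacing.
Coordinates are 0-based (row, col). Manual correction steps in the original
workflow are replaced by programmatic overrides; there is no GUI.

*Geometry.* Flank outlines offset the centerline along its normals by the
age-average half-width profile; the head region is the initial 20% of arc
length. Length is the centerline arc length; volume and surface area come
from the solid of revolution of the half-width profile (`π∫w²ds`, `2π∫w ds`,
trapezoid rule).

*Straightening and unit worm.* Straightened images sample the frame by
bilinear interpolation along perpendiculars at each 1-px arc step (rows =
head→tail, columns = signed offsets); samples outside the outline or frame
are flagged invalid and excluded from all statistics. Unit-worm warping
bilinearly rescales onto a fixed 100×24 grid (a resolution/speed
compromise), one standard per integer age, nearest age with a warning when
missing.

*Longitudinal registration.* A monotone 5-control-point warp (endpoints
fixed at 0 and 1) stretches/compresses the row axis; lateral displacement is
deliberately excluded. The fit maximizes `corr(image∘warp, reference) −
λ·Σdᵢ²` by coordinate-wise hill climbing with step halving from 0.05 to
0.005 of arc length, stopping when no single-coordinate move improves the
objective. The quadratic penalty (λ default 1.0 in correlation units) keeps
the objective smooth; a vulva anchor, when present on both images,
initializes the middle control point. A constant-intensity image (undefined
correlation) yields the identity warp with a warning. Population alignment
alternates the validity-weighted mean image (E step) with per-image warps to
the mean (M step) until the mean changes by less than 1% of its dynamic
range (this tolerance chosen so that convergence typically takes 2–3
iterations on warped-template populations) or an iteration cap.

*Expression PCA.* After alignment each image's mean intensity is subtracted
(invalid pixels then set to 0), the across-image mean image is removed, and
components come from the SVD of the centered image matrix — equivalent to
the Gram-matrix eigendecomposition, appropriate when pixels ≫ images. Each
component is signed so its mean loading over the head region (first 20% of
rows) is positive, making positive PC1 scores indicate head/vulva/tail-
specific expression and negative scores diffuse expression. Scores are
projections divided by the training-score SD, i.e. SD units; training scores
are mean 0, SD 1 by construction.

*Motion.* Four statistics over in-animal pixels: the fraction whose relative
intensity change `|a−b| / max(mean(a,b), ε)` exceeds 18% — the symmetric
pair-mean baseline is a design choice, averaged over all unordered frame
pairs within a condition — and the mean pixel-wise CV (sample SD / mean
across the frame set), each computed separately for pre- and
post-stimulation frame sets. All provided frames enter, not a fixed pair.
These feed a ν-SVR (RBF; C = 10, ν = 0.8, γ = 0.3) mapping to days of life
remaining; the reported score for each record is the prediction of a model
whose training folds excluded that record (k-fold, default 100, features
standardized within the training fold).

*Texture.* 17×17 patches inside the outline, per-patch mean removed, are
pooled into 2-day age bins (3–4 … 15–16; later ages reuse the last bin) and
k-means clustered to 30 textons per bin, 210 overall (500k samples per bin
in the original protocol; default scaled to 20k for desk-scale runs, the
count is configurable). An image's texture signature is the normalized
histogram of nearest-texton (Euclidean) assignments over a stride-4 patch
grid anchored at the first valid center; the same ν-SVR contract (C = 5,
ν = 0.6, γ = 0.004) maps signatures to days remaining. Optional linear
unmixing for autofluorescence bleed-through into the GFP channel exists but
is off by default (the effect is small and does not change conclusions).

*Calibration and pairing.* Fluorescence frames are corrected as
`(raw − dark) / (flat normalized to unit mean) / exposure`, negatives
clipped; nonpositive flat-field pixels are an error. Brightfield partners
for each fluorescence frame are chosen by maximal mutual information of the
64×64-bin joint intensity histogram, ties to the earliest frame. Exposure
bracketing reduces to "longest non-overexposed" in the reader.

## Statistics

OLS is fitted on z-scored predictors and response, so coefficients are
standardized β weights; R², F and p are invariant to that scaling and
predictions are returned in lifespan units. p-values use the F
distribution with (p, n−p−1) degrees of freedom via
`F = R²·df_err/((1−R²)·df_model)`. No multiple-testing correction is
applied, matching the analysis convention of reporting raw p-values.
Collinear designs (condition number > 10⁸) are rejected naming the
offending pairs. Leave-one-out R² uses the exact hat-matrix identity
`e_i/(1−h_ii)` (verified against n refits to 10⁻¹⁰). The survival
prediction index is the standardized-weight OLS over seven predictors:
length mean/slope, motion mean/slope, texture mean/slope, autofluorescence
slope. Dichotomization about the mean reports sensitivity, specificity, the
cohort mean-lifespan ratio and a two-sample two-tailed KS comparison. The
KDE uses Gaussian kernels with kernel *variance* σ̂²·n^−0.2 (the
rule-of-thumb as used in this analysis; note it is wider than the textbook
univariate Scott factor, which would scale the variance by n^−0.4).
Percentile summaries use linear interpolation, fixed. Window summaries use
only observed in-window points — no interpolation of missing days; the
slope is undefined (not zero) below two points. Aggregation across trials
is pooled-raw by default; per-trial centering is available.

`partial_r2_table` residualizes both the biomarker and lifespan on each
control set by OLS and reports the squared residual correlation as a
percentage of the uncontrolled R².

## Network inference

The skeleton search starts from the complete graph and, for conditioning
sizes k = 0, 1, …, tests each remaining edge (X, Y) against every size-k
subset of either endpoint's other neighbors, removing the edge as soon as
one test accepts independence. The CI test is the t test on X's coefficient
in the OLS regression of Y on {X} ∪ S ("multiple-regression independence
test"), α = 0.001 — under Gaussianity this is the standard partial-
correlation test, and it is brute-force checkable by exhaustive subset
enumeration on small graphs. Processing order is fixed lexicographic for
determinism; a "stable" variant (collect all removals per k before updating
adjacency) is available. Orientation phases are deliberately omitted —
edge directions were not robust in the source analysis and only the
undirected structure is used. Consensus over datasets: an edge is solid if
present in every network containing both endpoints (absent nodes do not
veto), dashed if present in some, and a node is unplaceable if it has no
edge anywhere it appears.

## Time-resolved prediction

For each age n in 2…7, the raw values from the biomarker's first measured
day (day 2, or day 3 for measures defined only from day 3) up to n, plus
all unordered pairwise products including squares (d + d(d+1)/2 features —
the products let a linear model express rates of change), are ridge-
regressed on lifespan. Predictors are standardized; the intercept is
unpenalized; the penalty minimizes `GCV(λ) = n·SS_res(λ)/(n − tr H(λ))²`
over a 50-point log grid 10⁻⁴…10⁴ (grid exposed in config), computed from
one SVD per design. Interaction terms stay within one biomarker; crossing
biomarkers would change the per-biomarker interpretation of the curves.
R² is reported in-sample at the chosen λ (an honest train/test split is
available but off by default, matching the headline definition); the GCV
penalty is what keeps the growing feature count from inflating it, and the
values can still be mildly optimistic relative to the two-summary models.

## Numerical and degenerate-input conventions

Bilinear interpolation everywhere; invalid pixels excluded from
correlations, means and percentiles; percentile interpolation linear;
lifespans generated and stored in days (hour-level estimation is a reader
concern); ties in frame pairing go to the earliest index; k-means and SVR
seeds derive from the caller's seed; identical seeds give bit-identical
tables and images. Degenerate cases raise informative errors rather than
silently continuing: empty masks, coincident head/tail seeds, disconnected
masks, zero-length centerlines, single-class training sets, constant
columns, degenerate dichotomization splits, zero-variance KDE inputs.

## Limitations

The synthetic cohort is linear-Gaussian by design: nonlinear aging
trajectories, heteroscedastic noise, left-skewed lifespan distributions and
measurement dropout are out of scope, so recovery results bound what the
statistics do under their own assumptions, not under real-data violations.
The image generator's idealized contrast makes the pixel classifier nearly
perfect; real brightfield segmentation would need richer features and
training data. Survival-curve modeling (Kaplan–Meier/Cox) is deliberately
absent — distributions and KS comparisons are the chosen representation —
and censored animals are excluded from regressions rather than modeled.
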