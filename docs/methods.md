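# Methods

This note records the models, conventions and design choices behind
`holocyte`, at the level of detail a user needs to interpret its output
or to reproduce a number it prints.

## Phase-shift images and units

All images are 2-D maps of optical phase shift in **radians**; files in
other instrument units are converted at import by a configurable scale
factor (`calibration.unit_scale`). Physical thickness uses
*t* = φλ/(2πΔn) with defaults λ = 0.635 µm (the common 635 nm diode) and
Δn = 0.04, the assumed constant refractive-index difference between cell
and medium. Both are configurable; Δn is an approximation — cells are
optically heterogeneous — so thickness and volume are *optical*
estimates, comparable within an experiment rather than absolute.

## Segmentation

Foreground is `pixels > threshold`. The default threshold is Otsu's
method over a 256-bin histogram of the observed range: the cut
maximizing the between-class variance, returned as the boundary between
the two classes' bins (hence shift-equivariant under constant offsets).
A fixed threshold can be supplied instead (`segmentation.threshold_mode
= "fixed"`), mirroring acquisition software that applies a fixed
instrument-unit cut; published values such as "130" are in proprietary
instrument units, so no radian equivalent is claimed here. Components
are 8-connected — stated explicitly because it changes object counts —
and components under `min_size_px` (default 26) are discarded. Touching
cells merge into one object; no watershed declumping is attempted.

Object boundaries are "crack" polygons traced along pixel edges, so an
n×n-pixel square has perimeter exactly 4n·pixel_size. The perimeter
feature counts all exposed pixel edges (holes included); the exported
polygon is the outer loop.

## The 26-feature panel

Feature names (with units) follow the fixed canonical, alphabetical
order in `holocyte.features.FEATURE_NAMES`. Definitions chosen where the
originating acquisition software's are proprietary — what matters for
classification is that they are computed consistently:

* **Area** = pixel count × pixel area. **Perimeter** = crack length.
* **Boxed length/breadth** = side lengths of the minimum-area rotated
  bounding rectangle of the pixel corners (length ≥ breadth).
* **Eccentricity** = √(1 − λ₂/λ₁) of the second central moments of the
  pixel coverage; a 1/12·I per-pixel term makes a single pixel isotropic
  (eccentricity 0) and keeps the value in [0, 1).
* **Shape convexity** = area / convex-hull area; **Hull convexity** =
  hull perimeter / crack perimeter; **Irregularity** =
  P/(2√(πA)) − 1 (0 for a disk, by construction using the crack P it is
  ≈ 0.128 even for a square).
* **Thickness avg/max, Volume** from the thickness map; **Phaseshift
  min** and **Phaseshift std. dev.** (population sd) from raw phase.
* **Roughness avg/skewness/kurtosis**: residual of the phase image minus
  its 5×5 mean filter (`mode="nearest"`), restricted to the object;
  mean absolute residual, then bias-uncorrected sample skewness and
  *excess* kurtosis (Gaussian → 0; zero-variance residuals → 0 by
  convention). The mean filter reproduces linear ramps in the interior,
  so smooth tilted cells read as flat. Whether instrument "roughness"
  acts on height or phase residuals is unspecified upstream; the phase
  residual map is this package's declared definition.
* **Texture (10 statistics)**: gray-level co-occurrence matrix with 32
  levels quantized over the object's own observed range, distance 1,
  four symmetric offsets (→, ↓, ↘, ↙) counted only where *both* pixels
  belong to the object; per-offset matrices are symmetrized, normalized,
  and averaged (offsets with no valid pair are skipped). Statistics:
  contrast, correlation, energy (angular second moment), entropy
  (natural log), homogeneity (inverse difference moment), max
  probability, cluster shade and cluster tendency (third/second moments
  of i+j about the marginal means), and the two information measures of
  correlation. A constant object yields the single-entry matrix
  (energy 1, entropy 0, contrast 0, correlation and both information
  measures 0 by convention) so degenerate cells never produce NaNs.

### Feature-independence selection

For each experiment table, |Pearson r| is computed per feature pair;
pairs involving a zero-variance feature are skipped for that experiment.
The across-experiment matrix takes the **minimum** |r| per pair — a pair
is only redundant if it stays correlated in *every* biological
condition. Greedy elimination walks features in canonical order and
drops the later member of any pair whose minimum |r| exceeds the cutoff
(default 0.98); declared constant multiples and positional metrics are
removed up front via an exclusion list. The shipped 26-name panel is
taken as given; the procedure is provided for re-derivation on new data.

## Frame-quality metrics

BgAv, BgSD and SNR are computed over the background/object partition
produced by segmenting *the same frame* — background is every pixel not
in a segmented object. BgSD uses the population (1/N) divisor, matching
the metric's printed definition. SNR is in dB (20·log₁₀). Undefined
cases (zero background spread, no object pixels, object mean not above
background) carry an explicit flag instead of a sentinel value. The
frame gate keeps BgSD ≤ `quality.max_bgsd` (default 0.5, in image
units); `bgsd_threshold_sweep` re-evaluates a classifier at cutoffs
{0.45, 0.5, 0.55, 0.6} and reports a cutoff as infeasible if it removes
every frame of some class.

## Classifier

Pipeline: per-feature standardization (needed because units span µm² to
dimensionless) → LDA to d = min(3, K−1) dimensions → full-covariance
K-component Gaussian mixture fitted by EM **without labels** (10
restarts, tolerance 1e-6, seeded) → components matched to states by
maximum-agreement optimal assignment (Hungarian) on the training labels.
Posteriors are mixture responsibilities routed through that map.
Training tables are bootstrap-balanced (default 1000/state) so mixture
weights reflect state structure, not group sizes. If the within-class
scatter is singular the fit falls back to a shrinkage-regularized eigen
solver with a warning.

Reported accuracy is **macro** (unweighted mean of per-class
accuracies), the natural choice under class-balanced training; pooled
accuracy is also available. Serialization stores the standardization,
the LDA map in affine form (W, b), the mixture parameters and the
component→state map in one JSON document; the estimator itself predicts
through the same affine constants, so a reloaded classifier reproduces
predictions bit for bit.

The `GaussianBaselineClassifier` fits one Gaussian per state on 1–3 raw
features with equal priors — supervised, because unsupervised mixtures
on such poorly separated axes do not yield usable classifications. It
exists to quantify what small feature panels miss.

## Kinetics

Tracking is greedy nearest-centroid under a `max_step_um` gate:
continuation links are assigned in order of increasing distance (ties by
object order); a leftover next-frame object whose nearest gated
predecessor already has a continuation converts that predecessor into a
division (both successors start daughter tracks); tracks without a
successor end as death/exit; ungated new objects start fresh tracks.
Probabilities are assigned per hour independently, frames removed by the
BgSD gate become missing values, missing values are linearly
interpolated (never extrapolated beyond track ends), the series is
smoothed with a Savitzky–Golay filter (degree 2, window 5 — exact on
quadratics; shorter series pass through), clipped to [0, 1] and
renormalized per hour.

Super-metric conventions where the verbal definitions leave latitude:

* **Pre-apoptotic indicator** — mean of smoothed P(St) over cell-hours,
  with P(St) pinned to 1 from the death hour to the end of the
  experiment (death is the terminal outcome the St state predicts).
  **Growth-arrested indicator** — mean smoothed P(CDKi) over observed
  cell-hours only.
* **Division rate** — division events / track count (per-cell);
  a per-cell-hour variant is available via configuration.
* **Mortality** — dead tracks / (dead tracks + tracks alive at the final
  frame); tracks ending in division continue as their daughters and are
  excluded from the denominator.
* **Motility** — fraction of cell-hours with hourly displacement above
  the hypermotility threshold. "Hypermotility" has no published
  definition; the default threshold is 2× the median hourly displacement
  of the control condition, configurable.
* **Variability of response** — mean of the across-cell population
  variances of four per-cell summaries (mean P(St), mean P(CDKi),
  division count, motility fraction), each min–max scaled to [0, 1]
  across cells first so quantities with different units average
  meaningfully.

Normalization divides each metric column by its across-condition mean
(idempotent; zero-mean columns are flagged and left as-is). Clustering
is UPGMA (average linkage) on Euclidean distances over four metrics
(pre-apoptotic, growth-arrested, mortality, division rate) by default;
all six are available. Trees export as Newick.

## Synthetic scenes: what they emulate, and what they do not

Cells render as elliptic-paraboloid phase caps, phase(r) =
peak·(1 − r²) over the normalized elliptical radius — smooth, strictly
positive inside, analytically integrable for oracles — plus
Gaussian-filtered white noise (scaled to a target amplitude) inside the
mask as texture. Background noise is i.i.d. Gaussian with sd =
`bg_sd_start + bg_sd_rate·t`, a linear stand-in for the observed upward
BgSD drift of an aging calibration; defaults (0.05 rad + 0.0125 rad/h)
cross the 0.5 gate near 36 h, consistent with calibrations staying
usable for roughly 40 hours. Background mean defaults to 0 (clean
calibration); a non-zero mean models miscalibration. Time-lapse
simulation applies per-hour death and division hazards (death checked
first), Gaussian motility steps, and places daughters one semi-minor
axis to either side of the parent along a random axis — separable but
linkable. Per-hour feature vectors are drawn from per-state 26-feature
Gaussians; `example_state_models` provides four plausible states (NT,
St, CDKi, M) whose means/covariances are **fixture parameters, not
measurements of any cell line** — the real states' distributions are
not public. A single seeded generator drives everything; identical
seeds give bit-identical frames, truth and tables.

Consequently, passing tests demonstrate correctness of the *computation*
(formulas, bookkeeping, recovery under known ground truth), not
biological performance: the renderer has no diffraction, speckle, focus
error or cell-shape irregularity, the feature distributions of rendered
cells are not those of real cells, and touching-cell declumping is out
of scope.

## Problem sizes and numerical conventions

Test and acceptance fixtures are sized for a laptop-class run: oracle
comparisons use 16–24 px tiles (200/100/50 repetitions for
quality/Otsu/GLCM), classifier recovery uses 1000 cells per state,
the filtering study 24 rendered 224² frames, and the kinetics screen six
conditions (NT/St/CDKi × 2 replicates) × 40 cells × 20 h without frame
rendering — 40 cells per condition matches the scale at which kinetic
screens are practical. Ties in Otsu are broken toward the lowest
maximizing cut; EM uses 10 restarts with a fixed seed; probability rows
are renormalized after clipping; all divisions by counts guard the
empty case and log or flag rather than emit NaN.

Known limitations: no declumping or track repair after occlusion;
greedy (not globally optimal) frame-to-frame assignment; the BgSD gate
assumes background pixels dominate the frame; thickness assumes a
single global Δn.
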