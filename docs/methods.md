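# Methods

This note documents the models, estimators, parameter defaults, and
numerical choices implemented in `smlm`, and what the synthetic-data
generators do and do not emulate.

## Coordinates, units, and data model

Localization tables are pandas DataFrames with columns `frame` (1-based),
`x`, `y` (nm, origin at the top-left of the field, y downward),
`uncertainty` (nm, the fitted localization precision, strictly positive),
`intensity` (photons), and `channel`. CSV I/O defaults to the
ThunderSTORM header convention (`"x [nm]"` etc.); a dialect registry
handles plain headers and µm-unit exports. Rendering uses 20 nm
super-resolution pixels and the camera grid uses 101.5 nm pixels; pixel
(i, j) covers the half-open square `[j·p, (j+1)·p) × [i·p, (i+1)·p)`, so
binning at boundaries is unambiguous, and square ROIs use the same
half-open convention (lower/left edges in, upper/right out).

## The five-step localization post-processing

Steps run strictly in order; each step only deletes or merges records.

1. **Duplicate removal** (same-frame): two localizations are duplicates
   when their distance is below the *larger* of their two uncertainties;
   groups are taken transitively (connected components) and the
   highest-intensity member is kept, on the reasoning that the brightest
   fit is the best-localized. The pairwise rule and the survivor choice
   are configurable.
2. **Uncertainty filter**: strictly greater than `max_uncertainty`
   (default 20 nm) eliminates; exactly 20 nm survives.
3. **Density filter**: neighbor counts are computed once on the input
   table (single pass, not iterated after removals — deterministic and
   matching common practice); default ≥ 2 other localizations within
   50 nm.
4. **Drift correction**: per-frame drift is the mean fiducial-bead
   displacement relative to each bead's first appearance, linearly
   interpolated across bead-free frames and smoothed with an 11-frame
   Savitzky–Golay filter of order 1 (equivalent to a moving average in
   the interior, with least-squares linear edge handling so a linear
   drift ramp is inverted exactly). The post-correction fiducial RMS is
   reported as a quality metric.
5. **Re-blink merging**: chains of appearances in consecutive frames
   (configurable gap tolerance, default 0) within 20 nm collapse to one
   record at the inverse-variance-weighted mean position, with summed
   intensity, the first frame index, and combined uncertainty
   `1/sqrt(Σ 1/σᵢ²)`.

Dual-color registration fits least-squares polynomials (degree 1–3,
default 2) mapping matched fiducial coordinates of the moving channel
onto the fixed channel; rank-deficient (e.g. collinear) control points
raise an error, and the control-point residual RMS is reported.

## Clustering-tendency statistics

**Hopkins index.** Squared-distance (d = 2) variant:
`H = ΣU²/(ΣU² + ΣW²)`, with `U` the nearest-data distances from `m`
uniform probe origins and `W` the nearest-neighbor distances from `m`
data points sampled without replacement (self excluded). Default
`m = min(⌈0.1·n⌉, 100)` with a seeded sampler — the standard
recommendation that keeps the estimator's variance stable across ROI
sizes. Expectation 0.5 under CSR; 1 in the coincident-point limit.

**Ripley's K/H.** `K(r) = A/(n(n−1)) Σᵢ≠ⱼ e(i,j) 1[dᵢⱼ ≤ r]`,
`L = √(K/π)`, `H = L − r`. Edge corrections: `toroidal` (exact periodic
distances; the default and the correction used in all calibration tests,
appropriate for synthetic windows), `isotropic` (Ripley circle-fraction
weights for ROIs cut from cells, evaluated by angular quadrature at
~0.5° resolution — numerically simple and accurate to ~0.3 %), or
`none`. The maximum radius is capped at half the window side.

## Bayesian cluster identification

Candidate labelings are generated on the published parameter grids:
radii `rseq = 5, 15, …, 195 nm` and neighbor thresholds
`thseq = 0, 5, …, 50` (grids are R-`seq()`-style, endpoints inclusive;
220 grid proposals plus the all-background baseline, deduplicated). For
each pair `(r, T)`: points with more than `T` neighbors within `r` are
retained, and clusters are the connected components of the retained
points at linkage distance `r`.

Each proposal is scored under a generative model: background
localizations are uniform over the ROI area `A`; cluster `c`'s
localizations are isotropic Gaussian around an unknown center with a
flat prior of density `1/A`, the cluster spread `s` carries a
log-uniform prior on [5, 150] nm integrated on a 30-point geometric
grid, and each localization's effective variance is `s² + σᵢ²` with
`σᵢ` its own fitted uncertainty. Centers are integrated out
analytically. The allocation prior sends each localization to background
with `p_background` (default 0.5) and partitions the clustered points
with a symmetric Dirichlet(`alpha` = 20) exchangeable prior
(Dirichlet-multinomial with one category per cluster), which penalizes
gratuitous cluster counts. The maximum-score proposal wins; score ties
break toward fewer clusters. The proposal/scoring scheme is a
deterministic search guided by the same generative model as the original
sampler-based formulation; its correctness surface in the test suite is
a permutation oracle (the true labeling must outscore shuffled ones) and
ground-truth recovery on simulated fields.

Descriptors: cluster radius = 2 × the RMS deviation of members from the
cluster centroid (configurable factor; for an isotropic Gaussian of
per-axis sd `s` the 2-D RMS deviation is `s√2`, so the reported radius
is `2√2·s` ≈ the visually apparent extent); molecules per cluster;
percentage of localizations in clusters. An optional frame-range filter
mirrors the practice of analyzing only the first few thousand frames to
bound processing time.

## Coordinate-based colocalization

For each channel-A localization, cumulative neighbor counts are taken on
10 equal-width rings out to `r_max` (default 70 nm, the nanocluster
radius scale): `D_AA(r) = N_AA(r)/N_AA(r_max) · r_max²/r²` with the
point itself excluded, and `D_AB(r)` likewise against channel B. A
channel-B localization exactly coincident with the scored A localization
is treated as the same molecule seen in the other channel and excluded
from the profile (it carries no neighborhood information); this makes
the identical-channels case score exactly +1. The colocalization value
is `C = ρ·exp(−E/r_max)` with `ρ` the Spearman rank correlation of the
two profiles (average-rank ties) and `E` the distance to the nearest B
localization. Localizations with an empty own- or cross-channel
neighborhood at `r_max`, or with a degenerate (constant) profile that is
not identical to the other profile, are assigned `C = 0`, so every
molecule receives a value. CBC is informative when the species are
locally structured; on very sparse unclustered data most profiles are
empty or degenerate and the statistic collapses to 0 by these rules.

## Single-particle tracking and diffusion

Detection band-passes each frame (Gaussian smooth of sd 1 px minus a
boxcar background over the feature window), finds local maxima above
threshold separated by at least the feature radius, and refines each
peak to sub-pixel precision with an intensity-weighted centroid on the
raw image above its local floor (the band-pass is for detection only —
its asymmetric support would bias the centroid). Detected coordinates
put pixel centers at integer positions.

Linking minimizes total squared displacement between consecutive frames
by optimal assignment with a birth/death cost of `max_disp²`
(displacements beyond `max_disp` are forbidden); unmatched tracks
persist `memory` frames. Tracks shorter than 10 points are discarded to
limit statistical noise. On small instances the assignment equals the
brute-force minimum over all permutations (verified in tests up to 6
particles/frame).

The MSD is time-averaged over all ordered pairs at each lag;
`D = slope/4` from an unweighted least-squares line through the first
three MSD points with a free intercept, which absorbs the static
localization-error offset. Negative estimates are reported as-is with a
flag rather than truncated. Mask-conditioned mobility uses a
majority-of-points rule (configurable to any/all) to call a track inside
a region, and reports per-group median `D` and the fraction below an
immobile threshold (default 0.01 µm²/s — a chosen operational cutoff for
"largely immobilized", configurable).

## Region quantification

Membrane masks come from a surface-marker channel: background mean +
k·sd (k = 2) with background taken from below the Otsu split, or plain
Otsu. Signal-high regions within the membrane use the membrane-pixel
mean + k·sd (k = 1); the low region is the exact set complement, so
high ∪ low = membrane on every input. Region statistics report pixel
area (µm²), total, and mean intensity per mask. Puncta counting
thresholds each z-section at 2× a supplied background, labels
8-connected components, and keeps area ∈ [5, 100] px² and circularity
`4πA/P²` ∈ [0, 1] with a Crofton perimeter (stable on small components;
values are clipped at 1); counts are summed over sections.

## MS hit filtering

Hits are keyed on UniProt accession. A protein is accepted when the
conjunction `log(e) ≤ −10 AND total peptides ≥ 5 AND unique peptides
≥ 2` holds within at least two replicate experiments (the conjunction is
applied per replicate, not criteria-wise across replicates), and the
protein is absent from every no-bait control — any observation in a
control excludes, the stricter reading. The peptides-per-kDa ratio
(`total_peptides / Mr`) is recomputed for accepted hits. The published
galectin-9 pull-down summary table ships as package data for reference
and testing.

## Synthetic data: what is and is not emulated

The generators provide ground truth for every stage. Clustered patterns
are a Thomas process (uniform parents, Gaussian offspring, Poisson
occupancy, uniform background) — deliberately matching the Bayesian
model's generative assumptions so recovery tests are well-posed.
Offspring clipped at the window edge are counted so edge-truncated
clusters can be excluded from descriptor comparisons. The emission model
gives each molecule a consecutive run of `1 + Poisson(mean_blinks − 1)`
frames starting at a uniform random frame (an on-time spanning frames —
the structure the merge step is built to collapse), log-normal
per-appearance uncertainties (strictly positive and right-skewed, as in
real fits), Gaussian position error of that sd, optional same-frame
duplicates, stage drift, and per-frame fiducial beads. Dual-color
patterns make channel A itself clustered (default 100 molecules per
cluster of sd 50 nm, 20 % background at 2000 points per channel —
localization densities typical of a 3 × 3 µm dSTORM ROI) and build
channel B from a controllable colocalized share of A plus independent
uniform points. Brownian tracks use per-frame displacements of sd
`√(2DΔt)` per axis at Δt = 0.05 s (20 frames/s) with *reflecting* window
boundaries (membrane-confined motion; periodic wrapping would create
teleporting displacements) and additive Gaussian observation noise.
Frames are rendered with pixel-integrated Gaussian PSFs and Poisson
noise.

Not emulated: dark-state photophysics beyond blink counts, chromatic
aberration beyond the polynomial warp, axial (3-D) structure, camera
read noise and gain statistics, and cell-shaped (non-square) ROIs.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative assumptions, not robustness to every property of
real cellular data.

## Problem sizes and determinism

Calibration and recovery runs use desk-scale sizes chosen to keep
Monte-Carlo error well below the decision thresholds: 200 patterns of
n = 1000 for the Hopkins null, 500 patterns for the Ripley null
(toroidal correction, radii 100–500 nm in 100 nm steps, acceptance at
two standard errors of the mean), 20 simulated fields for cluster
recovery, and 500 tracks of length 20 per diffusion regime. All
generators take explicit integer seeds and are bitwise reproducible; the
demonstration workflow derives independent per-stage substreams from a
single master seed.
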