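# Methods

## Scope and data model

`protrudyn` analyzes multi-channel 3D+time fluorescence stacks of single
amoeboid cells whose membrane/cortex is labeled by a cortically enriched
marker (the motivating marker is GFP–non-muscle myosin IIA). Stacks are
held as T×C×Z×Y×X arrays with physical calibration (µm voxel size,
seconds frame interval). All boundary analysis is performed on the 2-D
max-projection; the z dimension only contributes voxels to the cortical
section statistics. All tabular outputs are delimited text with a
`schema_version` column.

## Segmentation, tracking, boundary

Each frame is thresholded with the global Otsu algorithm on the
cell-marker channel and 3-D connected components are labeled; components
below a configurable minimum volume (default 20 voxels) are discarded.
Because Otsu always splits a histogram, a background-only frame is
recognized by requiring the foreground mean to exceed the background mean
by at least 4 background standard deviations (configurable). Cortically
enriched markers can threshold as a shell, so masks are hole-filled per
plane.

Objects are linked frame-to-frame by minimizing total centroid
displacement (Hungarian assignment) with a maximum linking distance
(default 10 µm); unmatched objects start or end tracks. Cells are motile
when tracked for ≥ 10 frames with average speed (path length / elapsed
time) ≥ 0.1 µm/s; slower active cells are jiggling; a curation flag marks
still (non-activated) objects. The rule-based still/active distinction is
a reproducible surrogate for manual curation, exposed as an
include/exclude flag rather than an automatic classifier.

The object boundary is the subpixel contour of the max-projection
(marching squares at the 0.5 level), optionally refined by an active
contour against the smoothed projected intensity (elasticity, rigidity
and iteration count are config; defaults were tuned on the synthetic
fixtures; a divergence guard falls back to the raw contour). The contour
is densified to 400 samples, smoothed by a short periodic Gaussian
(σ = 2 samples) to remove pixel-level jag, and resampled to exactly 100
points evenly spaced in arc length, oriented counterclockwise. Objects
touching the image border raise and are excluded as boundary defects.

## Per-point kinematics

*Correspondence.* Both frames carry 100 evenly spaced points, so the
order-preserving minimum-displacement assignment reduces to the cyclic
shift minimizing total displacement; the signed motion is the point
displacement, positive when the matched point falls outside the previous
polygon (exact point-in-polygon test).

*Local area change.* For point *k* the swept region is the hexagon
through the tracked point in both frames and the midpoints to its
clockwise and counterclockwise neighbors in both frames; its absolute
shoelace area is signed like the point's motion. Self-intersecting local
hexagons are flagged. On smooth deformations `Σ_k a_k` agrees with the
polygon area difference to well under 5% (measured ≲ 0.1% on the
fixtures).

Note that `a_k` deliberately includes whole-cell translation — a point on
the advancing front counts as protruding even while the local shape is
static. This matches the definition of local protrusion/retraction used
throughout and matters for protrusion lifetimes (below).

*Curvature.* The Pratt algebraic circle fit (generalized eigenproblem
with the B²+C²−4AD = 1 normalization) over the 11-point window centered
at *k*; κ = 1/R with the sign taken from the turning direction of the
window endpoints (positive = outward-convex). Collinear windows give
κ = 0. The fit matches a geometric (nonlinear least-squares) circle fit
to < 1e-6 relative radius on noiseless arcs.

## Cortical sections and normalization

The cortex is the band within 2 µm of the boundary. Every cell voxel
whose (y, x) column projects within 2 µm of the contour (distance to a
1000-point densification) is assigned to the section of the nearest of
the 100 boundary points; remaining cell voxels form the unassigned
region, so section counts conserve the total voxel count exactly. The
nearest-point rule replaces explicit section-polygon containment; for
smooth boundaries the two coincide except at ties, and the rule is
unambiguous and exactly conservative.

Normalization: `I_k(t) = (I_raw,k(t) − I_raw,min)/(I_raw,mean(t) −
I_raw,min)` with `I_raw,min` the per-cell minimum over all sections and
times and `I_raw,mean(t)` the mean over **all** cell voxels of the frame
(not only cortical ones — the alternative changes the scale of I, not its
structure). Flat frames (mean equal to the minimum) are flagged
undefined. Smoothing uses the voxel-weighted window `i = k−2 … k+1`
(four sections, cyclic); the asymmetric window is kept as the primary
definition, with `smoothing="symmetric"` switching to the 5-section
window `k−2 … k+2` for sensitivity analysis.

Regions: the rear is the 30-point arc centered on the point whose
outward direction is most anti-parallel to the migration direction, the
front the antipodal 30, the sides the remaining 2×20. Front/rear widths
are the spans of the arcs perpendicular to the migration direction.
Region levels are voxel-weighted means of the unsmoothed `I_k`. Frames
with undefined migration direction get undefined regions.

## Migration direction and correlation statistics

The migration direction `n(t)` is the unit two-frame displacement
`c(t+2) − c(t)` (undefined at the last two frames); the direction
autocorrelation `Corr(Δt) = ⟨n(t)·n(t+Δt)⟩` averages over all valid
pairs in the population. On correlated-random-walk fixtures the fitted
exponential decay recovers the generator's per-step heading correlation
within 10% at 50 cells.

Lagged Pearson correlations are computed on the offset-aligned overlap
(≥ 3 samples, zero-variance series flagged). The bootstrap resamples
time points of the overlap with replacement (default B = 1000, seeded); a
stationary block-bootstrap option exists because the series are
autocorrelated, but the plain bootstrap is the default since the original
resampling unit is unspecified. The lag of the peak correlation is
accepted as a characteristic offset only when the lower 95% percentile
bound at the peak exceeds 0.2; positive offsets mean the second series
(rear) lags the first (front). Front protrusion / rear retraction
magnitudes are the per-frame sums of positive `a_k` over front points and
of |negative `a_k`| over rear points.

Zero-centered correlation (for curvature or motion *x* against cortical
level *y*): `Cov′ = ⟨x·(y−⟨y⟩)⟩`, normalized by `√(⟨x·x⟩·Cov(y,y))`, so
the sign reflects association with positive versus negative *x*. `x ≡ 0`
gives 0 by the zero-numerator convention; constant *y* is flagged.

Threshold persistence: per cell, `f` is the fraction of frames with
`x > x_thr`; per experiment, `F` the fraction of cells with `f > t_thr`
(`t_thr` ∈ {0.5, 0.67}); curves report mean ± SEM of `F` over experiments
with a per-threshold one-way ANOVA across populations (scipy's
implementation of the classical sums-of-squares test). No
multiple-testing correction is applied across the threshold grid by
default.

## Protrusion detection and classification

A protrusion is born at a maximal cyclic run of points with
κ > 0.2 µm⁻¹ whose 5-point center (peak ± 2 points), mapped backward
through the point correspondence, shares no index with any qualifying run
of the previous frame. Centers are tracked forward through overlapping
runs (or the bare correspondence once curvature drops). The per-frame
rate is the summed `a_k` over the center window divided by the frame
interval; the lifetime ends at the first frame whose rate is negative
(beyond a configurable tolerance, default 0); events alive at the movie
end are right-censored and excluded from rate statistics. Classes:
transient (lifetime ≤ 6 s), stable (> 6 s), long-life (> 30 s); the
thresholds are configurable in seconds and converted by the movie's frame
interval.

The steady stage begins at the first frame whose rate falls below
ε = 10% of the event's peak rate (ε recorded in the output); the
expansion rate is the mean rate before it, the disassembly rate the mean
rate over the negative run after the lifetime ends. The E/S/R phase
durations derived from this rate profile are surrogates (flagged as
such): the exact steady-stage cutoff has no canonical value, and
whole-cell translation adds to the center's rate, so the rate-profile
E/S split shifts toward E for cells advancing into the protrusion.

The protrusion's myosin level `I'_protrusion(t)` is the voxel-weighted
mean over `i = k*−2 … k*+1` around the center index, averaged over the
lifetime; the localization lifetime is the longest consecutive run above
a threshold grid (default 1.1).

## Windows, directionality, states

Protrusion windows use global frame alignment: `start_index = Frame − 1`
(0-based), `total_frames = round(lifetime / frame_interval)`, the window
is `[start_index, start_index + total_frames)`, truncated and flagged at
the track end; E/S/R frame counts are applied sequentially inside it.

Directional parameters of the window's centroid subpath: ND (net
displacement), TPL (total path length), STA = ND/TPL, PR (mean cosine of
turning angles), ANGVAR (circular variance of turning angles), TI (mean
|turning angle|/π), TPθ for θ = 15°…85° in 10° steps (fraction of turns
exceeding θ), and average speed TPL/duration. These are standard motility
definitions, isolated behind one function so alternatives can be swapped;
windows with fewer than 2 steps are excluded.

All parameters are z-scored; near-constant columns (sd below 1e-10
relative) are dropped with a warning since z-scoring them amplifies
rounding noise. PCA by SVD; each PC's sign is anchored so its correlation
with ND is non-negative. The composite directionality index is the row
mean of the z-scores **with turning-type variables (ANGVAR, TI, TPθ)
sign-inverted**: a plain mean of oriented-both-ways variables would
anticorrelate with directional persistence, so the same
"invert so that higher = stronger directional migration" logic used for
PC1 is applied per variable. The median CDI splits protrusions into
high/low states (ties and the exact-median row go to low, so an odd
population gives ⌈n/2⌉ low). Transition probabilities
P(A→B) and run lengths are pooled over per-cell sequences ordered by
onset frame; rows without outgoing transitions are NaN.

## Synthetic data generator

The generator emulates a ~12 µm amoeboid cell (base radius 6 µm) as a
star-convex radial boundary: `r(θ,t)` = base radius + raised-cosine bumps
(half-width 0.35 rad) whose amplitudes follow the scripted E/S/R
schedule — linear ramp to the peak over E, plateau over S, linear decay
over R, with the first R frame still holding the plateau so the measured
"protruding or staying" lifetime equals E+S. An event with `angle=None`
forms at the heading of its birth frame, as pseudopods do. Amplitudes
above the base radius are rejected (star-convexity). The default
amplitude (1.5 µm) and half-width give peak fitted curvatures around
1 µm⁻¹, comfortably above the 0.2 µm⁻¹ detector threshold, against a
0.17 µm⁻¹ baseline.

The centroid follows a correlated random walk at constant step
(default 0.2 µm/s × 6 s) with wrapped-normal turning angles whose
concentration is set by the persistence parameter ρ (E[cos turn] = ρ, so
the direction autocorrelation decays as ρ^Δt). The cortical intensity
field is angular: uniform base (1.0 a.u.) + rear pool (2.0 a.u.,
raised-cosine of half-width π/3 opposite the heading) + front pool
(1.0 a.u. along the heading, fluctuating per frame with σ = 0.3); the
interior is 0.8 a.u. Rendering paints the field inside the true polygon
(cortex value within 2 µm of the boundary, interior elsewhere), blurs by
a Gaussian PSF (σ 0.2 µm), and applies Gaussian (σ 0.05) and optional
Poisson noise; default is a single z-plane since all analysis runs on
max-projections. Everything is deterministic given the seed, and
population fixtures derive per-cell seeds from a master seed.

The generator also emits boundary and intensity tables directly, so all
stages downstream of segmentation can be validated without rendering.

What the generator does **not** emulate: cortex mechanics, membrane
fluctuations below the bump scale, intensity–shape feedback,
photobleaching, 3-D shape, multi-cell fields, or collagen texture beyond
a static reference channel. Passing recovery tests therefore demonstrate
correctness of the measurement code under the stated statistical
structure, not robustness to every imaging pathology.

## Validation conditions and problem sizes

Recovery checks run at desk scale: 20 cells × 40 frames for protrusion
recovery, 200 subpaths for directionality, 50 cells for persistence
recovery, 100 null replicates at B = 1000 for bootstrap specificity, 50
random deformations for area bookkeeping, 100 arcs for the curvature
oracle. The protrusion-recovery fixture uses persistence 0.95 at
0.2 µm/s with front-placed events and retraction phases of 2 frames:
since the center rate includes whole-cell translation, lifetime recovery
against the scripted E+S requires that amplitude decay, not heading
reversal, determines retraction onset. With weakly persistent headings
(ρ ≲ 0.9) a real or simulated cell turning away from its protrusion ends
the measured lifetime early — that is a property of the lifetime
definition, not a detector failure, and is inherited by any analysis
built on it. Scripted lifetimes span 12–54 s (all phases must be ≥ one
frame, so sub-6 s transients cannot be scripted; transient
classification is validated on constructed rate profiles instead).

## Numerical choices

- Cyclic index arithmetic everywhere (mod 100); curvature windows,
  smoothing windows and center windows wrap the seam.
- Pratt fit: smallest non-negative generalized eigenvalue; |A| below
  1e-12 (relative) is treated as a line (κ = 0).
- Registration: upsampled phase cross-correlation against the first
  frame (fixed reference avoids drift accumulation), shifts applied to
  all channels with linear interpolation.
- Median split ties to low; PC sign anchor ND; bootstrap percentile CI
  (2.5/97.5); all RNG through `numpy.random.default_rng` with explicit
  seeds.
- Degenerate inputs are flagged rather than silently dropped: flat
  frames, zero-variance series, stationary windows, censored events,
  truncated windows.
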