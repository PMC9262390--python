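# Methods

This note documents the models, conventions, and numerical choices behind
`mitopolar`, and what the synthetic-data tests do and do not establish
about real microscopy data.

## Coordinate and angle conventions

Images are row-major with row 0 at the top. The anterior-posterior (AP)
body axis is the image vertical with anterior at the top, matching the
standard en-face presentation of embryonic head imaging. All angles are in
degrees relative to the AP axis, positive counterclockwise in the
anterior-up view. Two angle types are distinguished throughout:

* **position angles** in (−180°, 180°] — where on the cell perimeter a
  point sits, measured about the cell centroid (crescent centers live
  here);
* **axial angles** in (−90°, 90°] — undirected lines (spindle axes, cell
  long axes); θ and θ+180° are identified, and differences are always
  taken along the shorter arc. Folding to [0°, 90°] takes the absolute
  value.

The sign convention (positive = counterclockwise) is a package convention;
published rose plots report mirrored ranges without fixing a sign.
Reflecting an image about the AP axis negates signed angles and preserves
folded angles; the test suite asserts both.

## Synthetic mitotic domains

The generator stands in for live two-channel imaging of a mirrored pair of
mitotic domains. It emulates the *statistical structure* the measurement
chain must resolve, not tissue mechanics.

**Geometry.** Cells are 12-gons with ±8% radial jitter, centered on a
jittered hexagonal lattice clipped to two elliptical clusters mirrored
about the image midline. This is deliberately simpler than a Voronoi or
vertex-model tissue: the quantification operates per cell on traced
contours, so packing topology is irrelevant; non-overlap and realistic
perimeter curvature are what matter, and the lattice guarantees both (the
suite checks pairwise non-intersection). Interphase outlines are
area-preserving anisotropic stretches of the same polygons along a random
long axis with aspect ratio ~ N(1.3, 0.15) truncated at 1, typical mild
epithelial elongation.

**Cortical signal.** Along each boundary, the polarity channel follows a
von-Mises-shaped multiplicative modulation

    I(φ) = base · (1 + a · exp(κ(cos(φ − φc) − 1)))

with contrast `a` (peak elevation is exactly `a·base`) and concentration
κ controlling crescent width. Published images show single-peaked
crescents but no functional form; the von Mises bump is the smooth,
closed-form, single-peaked choice. A documented switch
(`double_sided_crescent`) adds the antipodal crescent, since the imaging
could not resolve whether the protein occupies one or both sides; the
default is single-sided. The membrane channel is the a = 0 limit and
shares the identical PSF/noise pipeline, making it a true control.

**Rendering.** Cell interiors are filled at the cytoplasm level; the
cortex is painted as a band with a flat-top cross-section (±1 px at I(φ),
Gaussian shoulder σ = 0.5 px), max-composited over dense boundary samples
so the band thickness is uniform and the pre-blur centerline equals I(φ)
regardless of rasterization. The PSF is an isotropic Gaussian (default
σ = 1 px); noise is optional Poisson shot noise followed by additive
Gaussian noise, applied last. Defaults: cortex base 200 a.u., cytoplasm
40 a.u., Gaussian noise σ = 10 a.u. = 5% of base — a clean-but-noticeable
live-imaging regime.

**Angles and kinematics.** Per side, crescent centers are
θc + N(0, 10°) with θc = +20° (left) / −20° (right), mirroring the
~20° mean tilt of oriented divisions; the final division angle is the
crescent angle plus N(0, σ_div = 10°), wrapped axially — so crescent and
division angle are strongly but imperfectly coupled, as observed. Spindles
assemble at a uniform random axial angle and rotate along the shorter arc
at a constant rate (10°/frame) toward the final angle, freezing at the
anaphase frame; the published observation is rotation "up to 90°" with no
kinematic law, so constant-rate shortest-path is the minimal model. With
the default 15 frames and anaphase at frame 12, every spindle (≤90°
travel) reaches its final angle before anaphase, so the truth table is
exactly recoverable. Spindle poles are two Gaussian blobs (σ 0.6 µm) at
±2 µm along the current axis.

**Determinism.** Every cell draws from its own `SeedSequence(seed,
spawn_key=(stream, cell))` stream: identical (config, seed) reproduce all
outputs bit-exactly, and enlarging the domain does not reshuffle existing
cells.

**What the generator does not emulate:** 3D tissue and projection
artifacts, cell rearrangement, cytokinesis, uneven illumination,
photobleaching, segmentation error in traced contours, and biological
covariates (cell-cycle stage, domain-boundary effects). Passing recovery
tests therefore demonstrates the *measurement chain* is correct and
well-conditioned at realistic noise, not that real data meet its
assumptions; real contours arrive via the contour-CSV interface and take
the identical code path.

## Profile measurement conventions

The manual tracing protocol leaves several details open; they are fixed
here as explicit conventions:

* sample spacing ≈ 1 px of arclength (the perimeter is divided into equal
  steps), bilinear interpolation; the transect at each sample averages
  `line_width` reads spaced 1 px along the local normal (default width 2,
  as in the protocol);
* the image is pre-smoothed with the protocol's 0.75-pixel Gaussian
  kernel (switchable);
* the trace start ("apical-most point" in side views) becomes the
  anterior-most contour vertex in the en-face synthetic view —
  configurable per contour via `reference_point`;
* traversal is forced clockwise (left-side cells) or counterclockwise
  (right-side cells) in the anterior-up view; enforcement reverses sample
  order, keeps the start sample first, and is idempotent;
* profiles are circular: resampling interpolates across the wrap point,
  and all statistics are invariant to rotating the start index;
* normalization divides by the mean cytoplasmic gray value (scalar or a
  polygon region averaged in the image) and must be positive; raw values
  are retained alongside.

Averaging is hierarchical: per-embryo mean curves first, then the
unweighted mean of embryo curves, so embryos with more cells do not
dominate — matching the per-embryo presentation of grouped results.

## Peak-to-trough statistic

"Adjacent troughs" is not defined in the source protocol. Implemented
reading: smooth the circular profile with a 5-sample moving mean
(configurable), take the global maximum (plateau ties resolve to the
plateau's circular midpoint), then walk in each circular direction to the
first local minimum; if both walks reach the same minimum it counts twice.
Peak and trough values are both read from the smoothed curve for internal
consistency. A constant profile gets P = 1 (not NaN) with a `no_peak`
flag, so uniform control channels aggregate cleanly while remaining
distinguishable. Because published mean ± SD values do not state the
aggregation level, summaries are emitted at both the cell and embryo
level, labelled.

## Division measurement

Pole detection smooths the frame (σ = 1 px), finds local maxima within
the contour mask, keeps the two strongest, and refines each to the
background-subtracted intensity-weighted centroid of a 7×7 window —
sub-pixel accuracy ~0.1 px on clean blobs, giving ≲0.5° axis error at
20 px pole separation. Anaphase is an explicit frame index (the source
protocol identified it morphologically; no automatic detection is
attempted). Rotation direction uses net shorter-arc displacement from
assembly to anaphase with a 1° dead zone for "none"; whether published
chirality fractions counted wobble or net rotation is unknowable from the
text, and the net-displacement rule is the documented reading. Rose
histograms default to 15° bins (bin width unstated in the source;
configurable) and always report percentages summing to 100.

## Ellipse fit

Second central area moments are computed by the exact polygon (Green's
theorem) formulas — region-based "fit ellipse" semantics rather than a
boundary least-squares fit, matching the measurement tool named in the
protocol. Axis lengths come from the moment eigenvalues (semi-axis
= 2√λ), then both are rescaled by a common factor so the ellipse area
equals the polygon area exactly; aspect ratio and orientation are
unaffected by the rescale. Fits with AR < 1.02 carry an
`unreliable_axis` flag: a near-circle's axis direction is numerically
meaningless. Because it is unstated whether long-axis angles were folded
before correlating with division angles, the long-axis-rule test reports
folded (primary) and signed variants.

## Inference

Mann-Whitney U uses the exact null distribution (standard count
recursion, cached per (n₁, n₂)) whenever the pooled sample is tie-free
and max(n₁, n₂) ≤ 20 — covering every per-embryo comparison at published
scale — and otherwise the normal approximation with continuity and tie
correction. The two-sided p is twice the smaller tail, capped at 1; under
complete separation this yields 2/C(n₁+n₂, n₁), reproducing the printed
minimal p-values. Spearman's ρ uses average ranks; its p is the exact
permutation probability for tie-free n ≤ 9 (cached rank-product null per
n) and the t-approximation with n−2 df above. Pearson r / R² are reported
alongside because published correlation panels print R² while declaring
Spearman coefficients; neither reading is asserted. Circular means use
the resultant-vector construction, with axial data doubled to period 180°.
No multiple-testing correction is applied (none is described for the
source analyses).

## Test-suite problem sizes and numerical choices

Calibration suites run 2000 null replicates at sizes chosen so the exact
tests' attainable size is essentially nominal: 8 vs 8 for Mann-Whitney
(exact size 0.0499 at α = 0.05) and n = 7 for Spearman and the
long-axis-rule test (0.048); coarser sizes (e.g. 10 vs 10, exact size
0.043) would sit below the nominal rate through discreteness alone, which
is a property of the test, not a calibration failure. Recovery suites use
3 embryos × 10 cells (the published profile-analysis design) for crescent
angles, a 100-cell noise-free cohort for division angles, and
256-vertex analytic ellipse polygons for shape. The mirror-symmetry
property uses a 2000-cell cohort. Floating-point plateau/flatness
comparisons use an absolute tolerance of 1e-12; the 5-sample moving mean
biases the 2 + cos(φ) peak-to-trough ratio below 3 by ~4·10⁻⁴ at 0.5°
sampling, hence the 0.01 tolerance on that contract.

## Known limitations

* The generator's cortical band (~2 px) is thin relative to the default
  PSF, so absolute profile values are dilution-scaled; normalized shapes
  and ratios are unaffected, but absolute normalized levels should not be
  compared against real data.
* Pole detection assumes exactly one spindle (two blobs) per contour and
  will fail informatively otherwise; metaphase-plate or 3D out-of-plane
  angles are out of scope.
* Rotation classification on wobbling spindles depends on the
  net-displacement rule; alternative readings (e.g. dominant-arc) would
  reclassify near-zero-net trajectories.
* Folded angles are compared with linear statistics (means,
  Mann-Whitney), matching the source analyses, rather than circular
  inference.
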