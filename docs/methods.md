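# Methods

This note records the conventions, parameter choices and known limitations of
`lingerlab`. It is written for users who need to know exactly what the code
computes, and for maintainers who need to know which choices were forced and
which were free.

## Geometry and coordinate conventions

The device is a symmetric diverging Y-bifurcation of rectangular
microchannels, width W = 9.6 μm, height H = 8 μm, channel length 120 μm,
branch angle 120°. The analysis frame puts the intersection center at the
origin, the parent axis along +x (flow in +x), and the daughter axes at ±60°.
The separation axis (SA) is the parent centerline, the x-axis.

Analysis positions are planar (single-focal-plane imaging); H enters only
through ROI volumes and flow cross-sections.

**ROIs.** Parent and daughter ROIs are rectangles of length 33.2 μm aligned
with their channel axes, starting 5.5 μm (measured along the axis) from the
intersection center. The intersection region I is the convex polygon bounded
by the three ROI near-edges and the channel walls (implemented as the convex
hull of the six near-edge corner points; point-in-polygon queries via
shapely, with boundary points counted inside). The three channel ROIs are
checked first, so a point is assigned exactly one label; everything else is
OUTSIDE. The exact shape of I is a convention — only its near-edge
boundaries are fixed by the ROI layout — and the residence-time statistic is
insensitive to the far details of the hull.

**Apex.** The flow-divider vertex is computed as the intersection of the two
daughters' distal walls (each offset W/2 from its axis toward the SA):
apex = ((W/2)/sin(θ/2), 0) ≈ (5.54, 0) μm for θ = 120°. This is consistent
with the 5.5 μm ROI offset: the ROIs begin essentially at the apex.

**Lateral coordinate.** y* = (signed lateral offset)/W ∈ [−0.5, 0.5]. In the
daughters the distal wall (the one meeting the apex) is +0.5 and the proximal
wall −0.5; in the parent, positive y* points toward daughter 1. Reflecting a
point across the SA therefore swaps the daughter labels, negates parent y*,
and preserves daughter y* and the apex distance. A configurable tolerance
(default 10⁻⁹, relaxed to 0.1 channel widths for jittered measurements in the
pipeline) guards against positions outside the wall.

**SA crossing.** A cell crossed the SA iff the sign of its parent-ROI y*
changes between two consecutive parent-ROI frames, using raw centroids (no
smoothing). Frames with |y*| at or below a dead band (default 0, i.e. only
exact zeros) are dropped before the comparison so that a frame sitting on the
axis neither counts as a crossing nor suppresses one.

## Classification

Residence time t_r counts *all* frames labeled I (re-entries included)
divided by the frame rate; cells that never enter I are excluded from
lingering statistics and logged. The reference time is t_ref = L/ū_out,0
with L the two-segment path parent-ROI exit → apex → daughter-ROI entry
measured along the channel axes (≈16.6 μm for the default geometry; either
daughter gives the same L by symmetry), and ū_out,0 the mean over cells of
each cell's speed at its last parent-ROI frame (one sample per cell, equal
weights — the averaging population at "the outlet" is otherwise unspecified,
and per-cell weighting avoids overweighting slow cells that linger near the
ROI edge).

Labels (LRBC/NLRBC):

- `tau`: τ = t_r/t_ref > 2.0, strict inequality, ties → NLRBC;
- `min_velocity`: u_min < u_thr, where u_thr defaults to the lowest-velocity
  local minimum of a Gaussian-kernel density (Silverman bandwidth, 512-point
  grid on [0, max u]) of all intersection speed samples, taken strictly
  between the two largest modes; a unimodal density raises an error and the
  caller must supply u_thr;
- `min_distance`: Δs_min < r_rbc (default 3.05 μm, the rabbit RBC radius);
- `rashidi`: the conjunction Δs_min < r_rbc AND u_min < u_thr.

The lingering frequency is count(LRBC)/count(analyzed), and the sensitivity
table re-evaluates it over τ cutoffs (default {1.7, 2.0, 2.3}); it is
non-increasing in the cutoff by construction.

## Hemodynamics

Units: lengths μm, speeds mm/s, volumes μm³, fluxes mm³/s; the only
conversion (μm² → mm² cross-sections) is centralized. Tube hematocrit per ROI
is the frame-average of count × MCV / V_ROI with MCV = 68.6 μm³ (rabbit
RBCs). The Pries–Secomb relation predicts Ht/Hr from the hydraulic diameter
Dh = 2WH/(W+H) = 8.7273 μm (displayed as 8.72 at two decimals); at
Hr = 10% it gives Ht = 5.50%.

Per-ROI mean speed is sample-weighted (all per-frame speed samples of all
cells in the ROI), matching a spatial-and-temporal mean; whether a
cell-averaged mean would be preferable is a genuinely open convention, and
sample weighting was adopted because it is what a stationary probe would
measure.

The conservation correction minimizes Σᵢ((Q̂ᵢ−Qᵢ)/Qᵢ)² subject to
Q̂₀ = Q̂₁ + Q̂₂. The closed-form solution (with d = Q₀−Q₁−Q₂ and
S = ΣQᵢ²) is Q̂₀ = Q₀ − dQ₀²/S, Q̂ᵢ = Qᵢ + dQᵢ²/S. Relative (not absolute)
adjustments treat the three measurements symmetrically regardless of
magnitude, and the correction is the identity on conserving inputs. Fractions
Φᵢ, Ψᵢ are ratios of corrected fluxes and sum to 1 exactly.

The capillary number is Ca = μ·ū/Gs with μ = 1.96×10⁻³ Pa·s and
Gs = 2.5×10⁻⁶ N/m; at ū = 0.67 mm/s the formula gives 0.525. (Published
values of ≈0.55 for these constants round differently; the implementation
returns the formula value.)

## Lateral distributions and the composite fit

LDFs are normalized histograms over [−0.5, 0.5] with an even bin count
(default 24, configurable; half-open bins, last bin closed), so a bin edge
falls on the centerline. Each cell contributes its y* at the inlet (first
frame) and outlet (last frame) of a ROI. The skewness index is the discrete
form Sk = |mass below 0 − 0.5|; samples exactly on the centerline follow the
half-open bin rule (counted above), a convention that only matters for
degenerate inputs.

The composite fit evaluates E(γ) as the bin-width-weighted sum of squared
*density* differences over bins with lower edge ≥ 0 — a Riemann sum of the
half-channel integral; the lower half-channel is excluded by default because
downstream target profiles of interest are typically contaminated there by
inflow from other vessels (the interval is configurable). Since the composite
density is affine in γ, E is exactly quadratic and γ̂ = Σw·a·b / Σw·b²
(a: target − NLRBC, b: LRBC − NLRBC) clipped to [0, 1]; ties in the
degenerate flat case resolve to the smaller γ by clipping. If the two
components coincide on the fit interval the weight is unidentifiable and an
error is raised. K–S and Mann–Whitney tests delegate to scipy
(`ks_2samp`, `mannwhitneyu`, two-sided, reporting threshold p = 0.05).

## Synthetic data generator

The generator emulates the *statistical structure* the analysis assumes, not
cell mechanics: piecewise-linear paths sampled at the frame rate, with
phenomenological speed profiles. Defaults reproduce the reference acquisition
conditions: 378 cells, 395 frames/s, 4000 frames, mean cruise speed
0.67 mm/s (per-cell CV 10%), lingering fraction 0.11, apex dwell uniform on
45–238 ms (only the observed range is known, so the maximum-entropy choice on
that interval is uniform), fair-coin branch choice, positional jitter
0.1 μm, multiplicative speed noise 3%.

Cell construction:

- **Entry (parent).** Lingerers enter near the centerline: |y*| from a
  truncated normal with sd 0.0625 (≈95% inside the central band |y*| < 1/8,
  matching the reported concentration of lingerers near the axis), floored at
  0.04 so measurement jitter cannot flip the sign. Non-lingerers enter
  off-center on either side: folded normal at 0.12 with sd 0.08 (≈52% inside
  the central band — off-center but far less concentrated), leaving a
  cell-depleted wall layer of 0.08.
- **Transit.** Non-lingerers cruise through the intersection (transit
  ≈ 20 ms ≈ 0.8 τ-units); those entering with |y*| below 0.07 are routed
  around the apex at a 2 μm closest approach without slowing — the "grazing"
  cells that defeat a pure minimum-distance criterion. Lingerers decelerate
  over 6 μm to a 0.03 mm/s hold speed, pin ≈1.4 μm from the apex for their
  dwell, then accelerate over 4 μm.
- **Branch.** Past the flow divider every cell relaxes to half its cruise
  speed (the flow halves at a symmetric split with equal cross-sections);
  lingerers exit slower still (0.35 × cruise), which reproduces the
  lingerer-induced downward bias of daughter mean speeds and hence the
  underestimation of daughter blood flow before the conservation correction.
- **Exit lateral position.** Lingerers marginate to the distal wall:
  y* ~ N(0.42, 0.04) (skewness index 0.50, essentially all cells in the
  distal band). Non-lingerers: y* ~ N(0.11, 0.13) (Sk ≈ 0.30, ≈45% in the
  distal band). These are calibrated to daughter-*outlet* profiles because
  that is where the composite-LDF components are measured.
- **Shape.** Circularity sits at 0.92 ± 0.015 in the parent, drops to ≈0.45
  while a lingerer folds at the apex, and relaxes logistically along the
  daughter; non-lingerers dip mildly in the intersection. Orientation follows
  the direction of motion folded to [−90°, 90°) with 4° noise.
- **Timing.** Each cell receives a random start frame so lingering events of
  different cells can overlap (needed for the concurrent-lingering split).

SA-crossing cells (probability 0.012 for non-lingerers, 0.33 for lingerers)
drift from their entry side to the opposite side within the parent ROI.

What the generator does **not** emulate: deformable-cell hydrodynamics,
cell–cell collisions, 3-D positions, tracking gaps and mis-assignments, and
intensity-based segmentation noise. Passing tests therefore validate the
*analysis chain* — metric computation, classification logic, flux algebra,
distribution fitting — under controlled conditions, not the biology of
lingering; on real tracks the τ threshold and the LDF shapes must be examined
per dataset.

## Numerical choices and degenerate inputs

- Strict inequalities at all classification thresholds; ties → NLRBC.
- KDE bandwidth: Silverman's rule (deterministic, exposed in the API);
  permutation-invariant by construction.
- LDF invariants enforced at construction: edges spanning [−0.5, 0.5]
  strictly increasing, non-negative mass summing to 1 within 10⁻⁹.
- The conservation correction rejects non-positive fluxes; fractional flows
  reject a zero parent flux.
- Track tables require ≥2 points per cell, strictly increasing frames, no
  duplicate (cell, frame) rows; speed may be tracker-supplied or recomputed
  from centroid displacements (central differences × fps).
- Determinism: one `numpy` Generator seeded from the config drives the whole
  synthetic experiment; equal seeds give byte-identical tables.

## Problem sizes

The test suite and the acceptance script run at desk scale: 60–400 cells per
synthetic acquisition (≈30–150 k track points), 200 fit replicates at 400
multinomial samples, and consistency checks up to 3200 cells. These sizes
were chosen so the full statistical checks (binomial 3-SD bands, ≥95%
recovery rates) are meaningful while the whole suite completes in well under
a minute.

## Known limitations

- Absolute τ values depend on the ROI convention (through L and the extent of
  I); comparisons *across criteria or thresholds* are unaffected. Published τ
  thresholds from other ROI layouts are not directly transferable.
- The intersection polygon construction is a convention; alternative hulls
  change t_r by at most a few frames per cell.
- The velocity-PDF threshold requires genuinely bimodal speed data; at very
  low lingering frequency the valley disappears and the threshold must be
  supplied.
- The composite fit assumes the target profile shares the bin grid of the
  component LDFs; resampling/interpolation of external profiles is the
  caller's responsibility.
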