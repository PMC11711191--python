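# Methods

## Coordinate and angle conventions

Images are indexed `(z, y, x)` with 0-based, half-open pixel boxes and
physical coordinates at pixel centers. Stacks default to the acquisition
voxel of 1.21 × 1.21 μm in-plane with a 10.62 μm z step. The outward
skin normal is an in-plane axis stored on every container (`+y` by
convention in phantoms; real data must declare it — no automatic surface
detection is attempted). Fiber orientation θ is undirected and lives in
[0°, 180°), measured from the normal: θ = 0° runs along the normal
("perpendicular" to the skin surface), θ = 90° runs along the surface
("parallel"). Thickness reports use mm, image-space code uses μm;
conversion happens only at report boundaries.

## Layer morphometry

A section is rotated so the normal runs along axis 0 (nearest-neighbor
on labels), then every column is a one-pixel strip. A layer's thickness
in a strip is its **pixel count** × pixel size — non-contiguous runs
(holes) are included, and strips without the layer contribute 0 rather
than being dropped, so deviations stay visible in the sd. Summaries are
mean ± sd over strips; the sd is evaluated on the shifted vector
`v − v[0]` so constant profiles report an exact 0. Tables print 2
significant figures with a machine-readable numeric CSV alongside.

## Preprocessing

The stack recipe is clip → blur → rolling-ball, in that order, each
appended to an audit log:

- **Clip** to [0, 4000] (the 12-bit display range used for these data).
- **Blur**: per-slice 2-D Gaussian, σ = 0.5 px, reflective boundary.
- **Rolling ball**: the background of a slice is its grayscale opening
  by a *spherical-cap* structuring element of radius 40 px (heights
  √(r² − d²) on a disk footprint), and the output is slice − background.
  This is the mathematical definition rather than any tool's
  shrink/enlarge approximation; the test suite holds it to exact
  agreement with a brute-force sliding min/max oracle. Opening is
  anti-extensive, so output ∈ [0, input] automatically, and idempotent
  as a background estimator.

Blur and ball are 2-D per slice because the z step is ~9× the in-plane
pixel; a 3-D structuring element has no physical meaning at that
anisotropy. All arithmetic is floating point; quantization to uint16
happens only on TIFF export.

The exact non-flat opening costs O(N · r²); at radius 40 that is
seconds for a 512² slice on one CPU. Analyses of *synthetic* stacks in
the tests and acceptance script therefore skip the ball stage — the
phantoms contain no slowly varying background for it to remove — while
the stage itself is exercised by its own oracle tests and by the
end-to-end pipeline on small slices.

## Intensity quantification

ROIs are fixed physical sizes (default ten ROIs of 200 × 250 μm with a
150 px boundary margin), placed uniformly at random in the admissible
region, pairwise non-overlapping (random sequential placement with a
retry budget; overlap rejection prevents pseudo-replication and can be
disabled). Means are taken on the maximum-intensity z projection by
default, matching the stacked-image view; per-slice analysis is an
option. Contrast between two samples is the fold change of grand means
plus the two-sample comparison below.

## Fiber extraction and orientation

1. **Ridge response.** For each scale σ ∈ {2.5, 5, 7.5} μm (bracketing
   the 5 μm default tube radius), the response is max(0, −λ₁)·σ² with
   λ₁ the more negative eigenvalue of the Hessian of the σ-smoothed
   slice; scales are combined by maximum.
2. **Salience threshold.** The retained support is the top
   `keep_fraction` (default 0.06) of *pixels* by response — the direct
   analogue of keeping the top 6% of transform coefficients in
   curvelet-based fiber analysis. An earlier variant that kept the top
   6% of response *mass* was rejected: on dense phantoms that cutoff
   lands deep inside the on-fiber response distribution, where the ~3%
   grid-orientation ripple of the discrete Hessian dominates retention
   and systematically favors axis-aligned fibers. Retention by pixel
   rank keeps the cutoff at the support boundary, where selection is
   orientation-neutral.
3. **Tracing.** The support is cleaned of components < 10 px,
   skeletonized, and decomposed into branches between skeleton nodes.
   Junction pixels are dilated by the expected fiber radius and
   clustered; clusters connected by bridge branches ≤ 30 px (the shared
   overlap segment two crossing tubes produce, up to width/sin(angle)
   long) are fused and the shared segments dropped. Incident branch
   ends are then re-paired greedily by straightest continuation (turn ≤
   40°), so an X crossing is traced as two through-going fibers rather
   than four stubs. Traces shorter than 20 μm (two fiber diameters) are
   discarded; polylines are Douglas–Peucker-simplified at 1-pixel
   tolerance.
4. **Angles.** Each fiber's θ is the direction of the total-least-
   squares (principal-component) line through its vertices. Percentages
   are per-fiber, not per-pixel. Window edges are inclusive;
   perpendicular = [0, 5] ∪ [175, 180), parallel = [85, 95]; the
   windows are disjoint by construction. Bimodal = both windows ≥ 20%.
   ROI-level analysis crops (default four 600 × 450 μm ROIs, 150 px
   margin), classifies per ROI and pools mean ± sd; a single-ROI call
   reports sd = 0 with a degenerate-sample warning.

## Crossing detection and density

A crossing is an event where two *distinct* fibers' polylines approach
within a contact distance (default the sum of their radii, i.e. 10 μm
for default tubes) with local in-plane tangents ≥ 15° apart — closer
than that is bundling, not crossing. Contacts of one pair within a
declustering radius (2 × contact) merge into one crossing at the
cluster centroid, making the count independent of polyline sampling.
Self-crossings are excluded. Densities use half-open ROI boxes
(crossings assigned by location containment), which makes counts
exactly additive across adjacent boxes; volume = in-plane extent ×
extruded depth (default 200 × 200 px × 100 μm).

For fibers traced from images, identity is unreliable: one physical
fiber may surface as several traces, so the same intersection can
appear under several pair ids, and trace stubs can touch another fiber
endpoint-first. Two options handle this: `decluster_scope="spatial"`
additionally merges crossings by location alone, and
`interior_margin_um` drops contacts closer than that arc length to
either trace's endpoint (a genuine crossing has both curves passing
*through* the contact). Defaults ("pair", 0) leave exact fiber sets
untouched; the recommended image settings (spatial, 10 μm) recover
planted counts within ~±10–15% at default noise.

## Statistics

Every two-sample comparison records Shapiro–Wilk normality per group
and Levene's variance-homogeneity test as diagnostics, then runs a
two-sided two-sample t test — pooled-variance when Levene does not
reject at 0.05, Welch otherwise (the diagnostics do not veto the test;
they are flags, and the fallback is logged in the result). Stars use
strict thresholds \* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001.
Constant-and-equal groups report p = 1. No multiple-testing correction
is applied; reports state the number of comparisons. Groups need n ≥ 3.

## Synthetic phantoms

**Layered sections.** Each tissue layer's per-column thickness is its
requested mean plus a sinusoid of amplitude `boundary_undulation_mm`
with 4 full periods across the width and a seed-determined phase, so
strip means average to the requested thickness and the strip sd of an
undulating layer is A/√2. Layers stack SC over VE over D over
background; a layer overflowing the image height raises a sizing error
naming it.

**Fibrous stacks.** Fibers are straight constant-radius tubes (radius
5 μm → 10 μm thick) lying in section planes — the out-of-plane tilt
bound is a parameter but defaults to 0, matching the 2-D-section
character of the analysis and keeping crossing truth exact (with a
10.62 μm z step and 10 μm contact distance, only coplanar fibers can
cross). In-plane angles are drawn from the three-mode mixture
(perpendicular window, parallel window, uniform elsewhere); lengths
uniform in 150–400 μm; intensity is a constant on-fiber scale (default
2000 of the 12-bit range) followed by an anisotropic generator PSF
(σ = 1 μm in-plane, 0 in z) and Gaussian read noise (σ = 5% of the
intensity scale, optional Poisson), clipped to [0, 4095]. Planted
crossings are added as coplanar pairs forced to intersect at ≥ 15°;
remaining fibers are rejection-sampled to keep 25 μm clearance from
existing fibers, and the emitted truth crossing count is computed by an
exact vectorized all-pairs pass over the final fiber list, so residual
incidental crossings are part of the truth. An all-parallel mixture
with a positive planted count fails with a generation error after the
retry budget, as it must.

**Intensity pairs.** Two stacks share one fiber geometry and one noise
distribution (absolute σ fixed by the base truth); the ventral on-fiber
scale is exactly `intensity_ratio` × the dorsal one before noise, and a
clip warning is recorded if it exceeds 4095. The default pair phantom
is dense — 500 fibers, ~40% areal coverage in one 1300² px slice, base
scale 600 — because dermal collagen in SHG images is dense and because
at sparse coverage the clipped-noise background floor, common to both
stacks, pulls the measured fold change toward 1 (at 3% coverage a
planted 2× ratio measures ≈ 1.6). Separation sampling is disabled for
pairs; overlapping tubes are realistic there and crossings are not
bookkept.

**What the phantoms do not emulate:** curved or branching fibers,
fiber-diameter variation, depth-dependent attenuation, polarization
dependence of the SHG signal, stitching seams, and real H&E color
variation (masks only). Passing tests therefore demonstrate that the
measurement chain recovers known geometry and intensity structure under
realistic sampling and noise — not that it is robust to every artifact
of real acquisitions.

## Problem sizes and determinism

Default analysis sizes in the tests and acceptance script: 300–1000
strip columns for morphometry; 200-fiber stacks of 20 × 512 × 512
voxels for orientation (≈7% areal coverage per slice); 50-fiber /
20-crossing stacks of 8 × 512 × 512 for entanglement; 1 × 1300 × 1300
pair stacks for intensity; 1000 null replicates at n = 10 for the
type-I calibration. These sizes were chosen so each stage's statistics
are well-resolved while a full run stays in the minutes range on one
CPU. Every random choice flows from a single `numpy` Generator seeded
from the user-facing seed; identical seed + parameters give
bit-identical phantoms, and the pipeline's report files contain no
timestamps, so a rerun reproduces them byte for byte.

## Known limitations

- Orientation percentages are per-trace; severe fragmentation (heavy
  noise, very low salience retention) would re-weight fibers by their
  pieces. The junction bridging also drops genuine fibers shorter than
  ~30 px that run between two junctions.
- The crossing rule is a geometric operationalization; it is not a
  topological linking or mechanical entanglement measure, and absolute
  densities depend on the contact-distance and angle thresholds.
- The rolling-ball implementation favors exactness over speed; for
  large production images a coarse-grained approximation would be the
  pragmatic choice, at the cost of the oracle guarantee.
- `run_pipeline` drives the synthetic study end to end; real-image
  studies are expected to use the library functions directly with
  `io.read_stack` / `io.read_mask` (units must be present — there is no
  silent default voxel size).
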