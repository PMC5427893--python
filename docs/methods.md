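# Methods

This note documents the models, conventions and numerical choices behind
vascumorph, and what its synthetic benchmarks do and do not establish.

## Synthetic vessel networks

The generator emulates the dorsal surface plexus of a rodent cortex as seen
in endothelial-dye preparations: a dense, largely planar, branching network
spanning both hemispheres. It is a seeded biased random walk with binary
branching:

- **Field**: 512×640 px at 20 µm/px (a 10.2×12.8 mm cortical slab).
- **Trunks**: 50 entry points on the image border, headed inward.
- **Steps**: 6 px per step with Gaussian heading jitter (σ = 0.35 rad),
  up to 110 steps per tip.
- **Branching**: probability 0.11 per step; the tip splits into two
  daughters at ≈ ±45°, making the branch point a junction (incoming
  segment + two daughters).
- **Widths**: per-trunk uniform integer in 3–6 px (60–120 µm), inherited
  by daughters.
- **Collision buffer**: every drawn segment stamps a clearance zone
  (width/2 + 3 px); a step whose endpoint lands in another branch's zone
  kills the tip. Because the step length (6 px) is smaller than any stamped
  stroke's diameter, a step cannot jump across an existing branch, so the
  network stays planar and the segment-level bookkeeping (junctions = points
  where ≥3 segments meet; length = Σ segment lengths) is exact.

These defaults were chosen to produce sham networks whose LFD histogram
peaks near 1.3 with a slight positive skew (a dense plexus with pockets of
high local complexity) at a foreground density of ≈0.18, and whose
rasterized/re-measured junction counts and total lengths recover the ground
truth within a few percent. Vessel density of ~18–20% and junction counts
in the hundreds per slab are realistic orders of magnitude for wide-field
imaging of the cortical surface at this resolution.

**What the generator does not model**: 3D geometry and projection effects,
vessel-calibre hierarchies (Murray-type branching laws), tortuosity beyond
heading jitter, staining heterogeneity, and imaging artifacts other than
additive Gaussian noise. Passing recovery tests therefore demonstrates the
*measurement chain* is unbiased on networks of known topology, not that the
generator reproduces real cortical anatomy.

### Lesion model

A segment whose midpoint lies at distance *d* from the epicenter is removed
with probability `max(g, c·falloff(d))`, with global fraction *g*, core
fraction *c*, and a falloff that decays linearly to zero at the lesion
radius (default) or is a top-hat. Defaults: epicenter in the right
hemisphere, radius 75 px (1.5 mm), *c* = 0.9, *g* = 0.3 — a focal
near-complete loss on top of a diffuse bilateral rarefication. Ablation
operates on segments, not pixels, so the post-lesion ground truth remains
exact.

**A measured property of this model (not a bug):** the kurtosis of the LFD
histogram responds non-monotonically to the global ablation fraction. At
*g* = 0.3 the distribution narrows slightly (kurtosis tends to *rise*,
6/24 paired replicates in the "fall" direction); at *g* = 0.4 mass spreads
down into the line-like LFD range and kurtosis falls (18/20). The
directional claims about fractal features are therefore exercised at the
strong-rarefication condition (*g* = 0.4, *c* = 0.9), while classical
metrics, ring gradients and hemispheric comparisons use the default lesion.

## Classical metrics

- Binarization: Otsu on the full image by default (a constant image is a
  degenerate-input error); a fixed threshold is available for
  reproducibility.
- Skeletonization: topology-preserving thinning (scikit-image).
- Junctions: a junction is a maximal 8-connected cluster of skeleton pixels
  having ≥3 skeleton neighbours, counted once per cluster — a crossing is
  one junction, matching how angiography tools display discrete junction
  dots.
- Length: traced per edge as inter-pixel steps, 1 unit orthogonal, √2
  diagonal, times the pixel size; an *N*-pixel straight path measures
  *N*−1 units. Redundant diagonal shortcuts next to an orthogonal bridge
  are not double-counted.
- **Spur pruning**: thinning a stroke of width *w* leaves terminal spurs up
  to ≈ *w*/2·√2 px at corners. The whole-image pipeline prunes terminal
  (endpoint-to-junction) branches shorter than 4.5 px — just above the
  artifact length of the widest default vessels — and junctions whose
  degree falls below 3 are reclassified. On raster toy skeletons the pure
  operation (no pruning) is used, where lengths and counts are exact.
- ROI restriction: a junction counts if its centroid is inside the ROI; a
  length step counts if both endpoints are inside.

## Local connected fractal dimension

For each sampled foreground pixel the connected component (8-connected by
default) of the foreground *restricted to the 31×31 window* centred there
is extracted; masses μ(ε) count that component's pixels within each
concentric ε-box (ε = 3, 5, …, 31), and the LFD is the least-squares slope
of ln μ on ln ε. Pixels with fewer than 3 distinct masses are invalid.
Values are clipped to [0, 2.2] (clipping logged). A global-component
variant sits behind `local_window=False`.

Numerical details worth knowing:

- μ(ε) ≥ 1 always (the centre pixel), so the regression abscissa is fixed
  and the slope is a precomputed dot product — this makes dense sampling
  (stride 1–2) affordable.
- A straight 1-px line yields exactly slope 1, a filled plane slope 2; on a
  level-7 Sierpinski raster the interior mean is ≈1.55 against a
  box-counting dimension of log 3/log 2 ≈ 1.585 — local estimates on a
  finite, boundary-clipped raster sit slightly below the global scaling
  exponent.
- Histogram features use bin width 0.01 on [0, 2.2]. The modal bin is
  located on a 5-bin moving-average of the histogram because the sham
  histogram's top is a plateau of near-tied bins (mode jitter between
  sampling grids is otherwise ~0.05–0.09); the reported peak frequency is
  the raw relative frequency at that bin. Kurtosis is the excess (Fisher)
  convention; skewness/kurtosis are moments of the LFD *samples*, not of
  binned frequencies.
- Default stride is 4 for exploratory whole-image maps; the experiment
  pipeline uses stride 2, where group-level feature estimates are stable.

## Analysis regions

mm→px conversion is `radius_mm × 1000 / pixel_size_um`, rounded half-up.
Ring 1 is the disk of the first radius, ring *k*>1 the annulus with
exclusive inner / inclusive outer radius, so rings partition the outer
disk. Rings are clipped to the cortex mask and each ring's clipped fraction
of its ideal continuous area is reported, so either clipping convention can
be reconstructed. The midline column belongs to neither hemisphere.
Mirroring reflects columns about the midline and drops out-of-bounds
pixels; in-bounds it is an involution.

## MR phantom, SWI and HRS

The phantom is an ellipsoidal brain (≈87 000 voxels at 32×96×96) in a dark
background, with a spherical-cap lesion centred on the dorsal brain surface
whose radius is solved by bisection so the realized lesion occupies the
requested fraction of brain voxels (±10% discretization; default 4%), and
a spherical hemorrhage core at the lesion centroid (default 0.3% of
brain). T2-like means: background 20, brain 120, lesion 180 (edema,
hyperintense), hemorrhage 60 (hypointense). The magnitude channel is flat
across the brain except the hemorrhage (60 vs 100 — short-T2* signal
loss), and the phase channel is zero apart from the hemorrhage (−1.8 rad)
plus slight noise. Susceptibility contrast thus comes from both channels,
as it does physically.

SWI follows homodyne practice: per slice, the complex image is multiplied
by the conjugate of its low-pass (k-space windowed by a raised cosine of
half-width 24 bins centred exactly on the DC bin — exact centring matters:
an off-centre window makes the low-pass complex and injects spurious phase
into a phase-free image). The filtered phase builds the mask
f(φ) = (φ+π)/π for φ<0, else 1, applied to the magnitude 4 times. Closed
forms: φ = 0 leaves the magnitude unchanged; φ = −π/2 scales it by
0.5⁴ = 0.0625. Note the homodyne step removes much of the phase *interior*
to a blob comparable in size to the filter resolution — this is why the
phantom's hemorrhage also carries a magnitude deficit, and why segmenting
hemorrhage from phase contrast alone is unreliable at phantom scale.

HRS preprocessing restricts to the supplied brain mask (standing in for
skull stripping; a threshold-plus-largest-component fallback would be
needed for real data) and linearly rescales masked intensities to [0, 255]
(inverse stored; leaf means are reported in original units, making the
segmentation equivariant to intensity shifts). Recursion: 256-bin
histogram, 5-bin moving-average smoothing, peak detection requiring
prominence ≥ max(3·√height, 5) — a Poisson-noise gate that rejects bumps on
the flank of a single mode while keeping genuine small compartments —
two tallest peaks separated by ≥10 intensity units, split at the middle of
the minimal run between them (the valley floor of well-separated modes is
flat, so the first minimum would bias the split toward the lower mode).
Stopping: coefficient of variation ≤ 0.05 (on rescaled values), region
< 2×50 voxels, unimodal histogram, or depth 6. When a region becomes a
leaf its 6-connected spatial components become separate leaves. Lesion
(or hemorrhage) = union of leaves whose mean lies within the meanTh
tolerance of the a-priori target; volume percent is relative to the brain
mask.

Phantom-calibrated defaults: T2 lesion target 180 ± 15 gives Dice ≈ 0.96
and recovered volume ≈ 3.7% on the 4% phantom; SWI hemorrhage target
30 ± 35 gives Dice ≈ 1.0.

## Statistics

Welch's t-test is the default two-group comparison (group sizes of 5–6
with no variance-homogeneity guarantee); the pooled Student variant is
available. ANOVA post-hocs multiply pairwise p by the number of pairwise
comparisons, capped at 1 (Bonferroni). Percent reduction is
100·(control−treated)/control, reported to one decimal. Correlations are
plain Pearson r² with two-sided p. Two groups that are both
zero-variance with equal means yield an undefined (flagged) test rather
than an arbitrary number. Under the null (normal, n = 6 per group,
10 000 replicates) the default test rejects at ≈0.050 at α = 0.05.

## Experiment pipeline

Per-subject seeds derive from one master seed via `SeedSequence` (kept
below 2³¹), so reruns are byte-identical. Each subject: grow network →
(injured only) ablate → rasterize (noise σ = 8 on background 30 /
foreground 200) → binarize → skeletonize/measure → one LFD map, read out
per region (whole, hemispheres, rings 1–3). Problem sizes — 512×640 px
fields, cohorts of 5+5, LFD stride 2, 10–20 replicates for Monte-Carlo
properties — keep the whole suite and the acceptance script to a few
minutes on one CPU while leaving group effects well clear of their noise
floors.

## Known limitations

- 2D only; no atlas registration (the epicenter is supplied in pixel
  coordinates); no vessel-diameter profiling; lacunarity not implemented.
- Between-subject variability of synthetic junction counts (CV ≈ 0.14) is
  substantial at n = 5; null-effect checks need the full field size to sit
  comfortably inside ±10%.
- The LFD histogram's modal location is intrinsically ill-determined
  (plateau top) to ~±0.05 at realistic sample counts; group comparisons of
  peak frequency are correspondingly the noisiest of the fractal features.
- HRS constants (bins, smoothing, prominence gate, CV threshold) are
  phantom-calibrated and echoed in every report; real MR data would need
  its own calibration and a true skull-stripping step.
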