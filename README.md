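# vascumorph

Quantitative morphometry of whole-cortex vascular networks, built for
studies of focal traumatic brain injury (TBI) where a cortical impact causes
both a local wipe-out of vessels at the impact site and a diffuse,
bilateral rarefication of the surface plexus. The package provides the full
measurement chain such a study needs — and, because no public image data
accompanies this kind of experiment, a synthetic-data module that grows
vessel networks and MR phantoms with *exact* ground truth so every stage is
testable end to end.

## What it computes

**Classical vessel metrics** (`vascumorph.metrics`) — AngioTool-style
analysis of a 2D fluorescence image of surface vasculature: Otsu (or fixed)
binarization, topology-preserving skeletonization, junction detection
(maximal clusters of skeleton pixels with ≥3 neighbours, one count per
cluster), total vessel length by inter-pixel step counting (an *N*-pixel
straight path measures *N*−1 units; orthogonal steps count 1, diagonal √2),
and vessel density (foreground area / ROI area).

**Local connected fractal dimension** (`vascumorph.fractal`) — at each
foreground pixel *p*, concentric square boxes of odd side ε are centred on
*p* and the pixel mass μ(ε) of the locally connected foreground component
containing *p* is recorded; the LFD is the least-squares slope

```
LFD(p) = d ln μ(ε) / d ln ε ,   ε = 3, 5, …, 31 px
```

≈1 for isolated vessels, →2 for space-filling tangles. The LFD histogram
(bin width 0.01 on [0, 2.2]) is summarized by the modal LFD ("peak LFD"),
the relative frequency at the mode ("peak frequency"), and the skewness and
excess kurtosis of the LFD samples. A global box-counting estimator is
included as an independent cross-check (it reproduces log 3 / log 2 ≈ 1.585
on a Sierpinski raster to machine precision).

**Analysis regions** (`vascumorph.roi`) — concentric 1-mm rings around the
injury epicenter (ring 1 a disk, ring *k*>1 disjoint annuli), hemispheric
halves about a midline column, and contralateral mirror ROIs.

**MR lesion analysis** (`vascumorph.mri`) — susceptibility-weighted imaging
(SWI): per-slice homodyne filtering against a centred 48×48 Hanning k-space
window, negative-phase mask f(φ) = (φ+π)/π applied to the magnitude four
times; and hierarchical region splitting (HRS): recursive bimodal histogram
splitting at the valley between the two dominant peaks, with lesion or
hemorrhage extraction by a-priori mean intensity (meanTh).

**Statistics** (`vascumorph.stats_report`) — percent reductions of group
means, Welch/Student t-tests, one-way ANOVA with Bonferroni post-hocs,
Pearson r² correlations, and a deterministic mean ± SEM report with
significance flags at p < 0.05.

**Synthetic data** (`vascumorph.synthetic`) — a seeded branching random
walk grows a planar vessel plexus with exact segment, junction and length
bookkeeping; a lesion model removes segments with probability
max(global, core·falloff(distance to epicenter)); an MR phantom provides
brain/lesion/hemorrhage compartments with matched T2-like, magnitude and
phase channels.

## Worked example

Run the full synthetic experiment — 5 sham and 5 injured subjects, each a
freshly grown 512×640 px (10.2×12.8 mm at 20 µm/px) plexus, the injured
group ablated at 30% globally plus 90% at a 1.5 mm-radius focal core —
then measure every subject and compare groups:

```bash
vascumorph run-all --seed 0 --out results/
```

prints the whole-cortex effect table (columns: percent reduction of the
sham mean, Welch t, p, significance at 0.05):

```
region          metric  percent_reduction  t_statistic  p_value  significant
 whole  junction_count               68.4     9.780578 0.000069         True
 whole        kurtosis               70.1    -1.740096 0.121829        False
 whole  peak_frequency                4.0     0.854289 0.426131        False
 whole        peak_lfd               12.5     3.894339 0.008772         True
 whole        skewness              617.9     9.063315 0.000020         True
 whole total_length_um               29.7     9.372076 0.000100         True
 whole  vessel_density               23.5     5.591517 0.000554         True
```

Reading it: the injured cohort loses about two-thirds of its vessel
junctions and a third of its total vessel length; the LFD histogram shifts
left (peak LFD down 12.5%), i.e. the surviving network is dominated by
simpler, more line-like structures. Per-region rows (hemispheres, rings
1–3) are in `results/metrics.csv` and `results/report.md`; the resolved
configuration, including every defaulted constant, is echoed to
`results/resolved_config.yaml`.

Single-stage commands work on any grayscale TIFF:

```bash
vascumorph simulate --seed 3 --n 1 --out sim/        # image + ground truth
vascumorph analyze sim/subject-sham-00.tif --out an/ # junctions, length, density
# -> junctions=342 length_um=326039.1 density=0.2029
vascumorph fractal sim/subject-sham-00.tif --out fr/ # LFD map + features
# -> peak_lfd=1.215 peak_frequency=0.0207
vascumorph mri --seed 1 --out mri/                   # phantom + SWI + HRS
# -> lesion volume = 3.71% of brain
```

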