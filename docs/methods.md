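# Methods

## The measurement problem

In the early *C. elegans* embryo the pericentriolar material (PCM) is built
from concentric protein territories around the centrioles: an inner sphere
delimited by the SPD-2/CEP192 scaffold, an outer sphere delimited by
SPD-5 (with γ-TuRC components at similar or intermediate extents), and a
toroidal AIR-1/Aurora-A territory that extends beyond both.  At mitotic
exit the PCM is removed in two steps: inner-sphere proteins *dissolve*
(their centrosomal intensity declines gradually), after which the aging
outer sphere is mechanically *ruptured* by cortical pulling forces — holes
appear, the centriole-connected volume drops, and individualized *packets*
are pulled away.  Meanwhile the centriole pair resolves into two foci
(Stage 1) that then separate by more than 1 µm (Stage 2).

`pcmkit` implements the quantitative side of that analysis for calibrated
`T×C×Z×Y×X` fluorescence movies, and — because no raw movies are publicly
available — a synthetic movie generator whose ground truth encodes the
published geometry and kinetics, so the entire pipeline can be validated by
closed-loop parameter recovery.

## Image quantification

**Background subtraction.** For each z-plane and timepoint, the mean of
`n_points = 10` randomly sampled cytoplasmic voxels is subtracted and
negatives are clamped to zero.  "Cytoplasm" is everything farther than 1 µm
from the previous frame's PCM mask (first frame: a relative-threshold
pre-mask at 25 % of the smoothed dynamic range).  Sampling is driven by a
seeded generator and the sampled means are logged, making an inherently
manual protocol reproducible.  With a background of ~50 counts the
10-point estimator has a standard error of ≈2.2 counts per plane, which
propagates to a 2–3 % per-frame standard error on centrosomal intensity —
this number sets the event-detection thresholds below.

**Segmentation.** A 256-bin Otsu threshold on the corrected stack's
histogram; voxels at or above threshold are PCM.  Two robustness measures
are applied by the pipeline (both can be disabled, and both are inert on
noiseless input):

* an in-plane Gaussian pre-filter (σ = 1 px) before thresholding —
  without it, shot noise in the late, dim frames produces supra-threshold
  cytoplasmic speckle that registers as spurious packets;
* the threshold is computed on a crop (default 3 µm laterally, 2 µm
  axially) around the centrosome, with a floor of 5 robust (MAD-based)
  noise standard deviations.  The acquisition protocol thresholds stacks
  taken *through the centrosome*; over a whole-embryo field the Otsu
  objective is dominated by the cytoplasm class and fails for an object
  occupying <0.1 % of the voxels.  The MAD floor keeps a nearly exhausted
  structure from being re-segmented as background speckle.

Because Otsu's threshold scales with the histogram, a structure that only
dims keeps a constant segmented volume — which is exactly the published
behaviour of the outer scaffold (intensity falls from 3 min, volume
constant until rupture) and is why the volume series is a meaningful
rupture detector.

**Volumetry.** 26-connected 3-D labeling; component volume is voxel count ×
dx·dx·dz.  Only components containing (or within one voxel of) a centriole
position count toward PCM volume; every other component is a packet.  This
automates the original manual subtraction of individualized packets.
Centriole positions come from the two brightest local maxima of the
centriole channel, or from ground truth in simulation.

**Intensities.** Total intensity is the sum over a box centered on the
centrosome minus the sum over an equal cytoplasmic control box (mirrored
across the field center, auto-shifted until disjoint).  The default box is
6 × 6 × 4 µm: the published 15 × 7.5 µm box is configurable but does not
fit the default synthetic field, and for a 4-cell-stage blastomere may
overlap neighbouring centrosomes.  Centrosome-contiguous intensity is the
corrected sum over the centriole-connected components dilated by 0.6 µm
(the automated stand-in for a manually drawn ROI around the thresholded
centrosome; 0.6 µm exceeds one z-step, so the axial fuzzy edge is
included).  Packet intensity is total minus centrosome, floored at zero.
On noiseless renders, total equals centrosome-plus-packet direct sums
within 2 %.

## Event detection

All onsets are reported on the acquisition grid (whole minutes at
dt = 1 min); cohort means may be fractional.

* **Dissolution** — the frame at which the sustained decline *begins*: the
  frame preceding the first frame whose intensity falls below the running
  maximum by more than `min_drop_frac`, sustained for 2 consecutive
  frames.  `min_drop_frac` defaults to 0.10: ≥4σ of the per-frame
  measurement noise (see above) while the true post-onset drop with a
  1.5-min half-life is ≥30 % per frame, so detection is neither early nor
  late.
* **Volume decrease** — first frame whose centriole-connected volume falls
  below the running maximum by more than 10 %.
* **Rupture** — two detectors, the earlier wins, both reported: (i) holes —
  newly background voxels strictly interior (one in-plane erosion) to the
  previous frame's connected component, in clusters of ≥4 voxels; this
  catches enclosed cavities and boundary-connected bites alike; (ii) a
  connected-volume drop of more than 15 % from its running maximum.
* **Packet formation** — first frame with a non-connected component of ≥3
  voxels with centroid within 5 µm of the centrosome.
* **Stage 1 / Stage 2** — per frame, the two strongest in-plane maxima of
  the (median-subtracted, σ = 0.7 px smoothed) centriole channel are
  refined to sub-pixel centroids; foci are resolvable when ≥2 px apart
  with an intensity dip of ≥20 % between them.  Stage 1 is the first
  resolvable frame, Stage 2 the first frame with separation >1 µm.

## Statistics

Ordinary least squares over stated windows (defaults: 0–4 min for the
inner scaffold, 2–4 min for the outer) with r² as squared Pearson
correlation; slope pairs compared with a Welch t-test on the slope
estimates and their standard errors (Welch–Satterthwaite df).  Group
comparisons: unpaired Welch t-test for two groups, one-way ANOVA followed
by Tukey's HSD for more, annotated * p<0.01, ** p<0.001, *** p<0.0001.
Time courses aggregate as mean ± s.e.m. per frame; a cohort of one reports
the s.e.m. as absent, not zero.

## The synthetic generator

Each channel is a radially symmetric field with a logistic edge of
softness w = 0.1 µm, so the half-maximum radius equals the nominal radius
analytically.  Control geometry (half-max radii, µm): centriole 0.25,
inner kinase 0.45, inner scaffold 0.575, intermediate γ-TuRC adaptor 0.72,
outer scaffold 0.83, γ-TuRC 0.84, toroid (0.48, 1.20).  Control kinetics
(min post-NEBD): inner dissolution 2.0/2.2/3.0 (kinase/inner/intermediate),
inner volume decrease 3.0, outer peak 3.0 (20 % linear rise from NEBD),
rupture 5.91, packets 6.5, Stage 1 5.0, Stage 2 6.429.  Decay is
exponential (half-lives 1.5 min inner, 2 min outer) toward a residual
floor (10 % of peak for control).

* Lateral pixel size 0.15 µm/px, z-step 0.5 µm, 1 min frames; default grid
  96(y) × 128(x) × 24(z) voxels × 12 frames.  The x-extent exceeds the
  y-extent so the total-intensity protocol's cytoplasmic control box fits
  disjointly beside the centrosome box.
* **Volume decrease** is rendered as mass-preserving compaction (radius
  shrinks 6 %/min, amplitude rescales by 1/shrink³): volume can fall
  before intensity does — as observed for the γ-TuRC adaptor — and
  shrink-induced intensity loss cannot masquerade as dissolution.
* **Rupture** carves two background-connected notches (radius 0.55 µm)
  into the shell equator, perpendicular to the centriole separation axis
  so the centrioles are never carved out of the component.
* **Packets** (count, speed, release geometry are unpublished and exposed
  as parameters): 4 foci of half-max radius 0.3 µm released at 1.4–1.8 µm
  from the center at jittered equal angular spacing, translating radially
  at 0.8 µm/min and decaying with a 1.5-min half-life (1.0 min for the
  γ-TuRC-like channel, which loses its association first).
* **Centrioles**: a single 0.25-µm focus that splits into two 0.15-µm foci
  at Stage 1 (0.6 µm apart, drifting at 0.1 µm/min) and jumps to >1 µm at
  Stage 2; separation is capped at 1.3 µm so both centrioles stay inside
  the outer sphere.
* **Noise**: uniform cytoplasmic background (50 counts) with 2 % per-plane
  jitter, Poisson shot noise with gain g (var/mean = g over a uniform
  patch), additive Gaussian read noise (σ = 1), clamped at zero.
* **Inter-embryo variability**: published per-embryo onsets are integer
  multiples of the 1-min frame interval (every printed cohort mean is a
  rational k/n of integers); the generator therefore realizes each movie's
  onset as floor(mean) or ceil(mean) with probability equal to the
  fractional part.  The uniform behind that choice comes from a
  golden-ratio low-discrepancy sequence keyed on the seed, so any ~10
  consecutive seeds reproduce the cohort-mean onsets to within ~0.1 min —
  without this stratification a 10-movie cohort mean would carry ±0.13 min
  of binomial sampling error on top of detection error.
* **Condition presets**: *gpr-1/2*(RNAi) removes rupture and packets,
  delays Stage 1/2 to 9.091/12.100 min and raises the outer residual to
  24 % (≈2.4× control, the published residual-intensity ratio);
  *csnk-1*(RNAi) advances rupture to 5.4 min and Stage 1/2 to 4.714/5.714
  min and scales the outer amplitude to 0.85×; *let-92*(RNAi) (abstracted
  from the one-cell zygote onto the same grid) slows decay 5-fold, sheds
  long-lived (6-min half-life) packets from both scaffolds without rupture
  holes, and leaves a 25 % residual.

**What the generator does not emulate:** optics (no PSF convolution — the
logistic edge is an effective profile, not a diffraction model), spindle
and chromosome signal, neighbouring centrosomes, cell movement or drift,
photobleaching, and the AIR-1/TPXL-1 microtubule spreading.  Passing the
recovery tests therefore shows the pipeline is correct and unbiased under
realistic shot noise and frame quantization; it does not show robustness
to segmentation-adjacent structures or drift, which real data would add.

## Validation strategy

Every operator is tested against an independent oracle: 26-connected
volumetry against a brute-force flood fill, the Otsu threshold against an
exhaustive 256-bin between-class-variance scan (equivalence is asserted on
the objective because the objective is flat across empty histogram gaps),
slope fits against the normal equations (1e-10), Tukey p-values against a
studentized-range recomputation, the overlap statistic against quadrature
of the projected-sphere chord (≈80.5 % of the outer-scaffold area falls
within the inner-sphere window when the sphere support is the reference
interval; the published real-data value is 77.8 ± 0.8 %), and the
background estimator against Poisson sampling theory.  Closed-loop
recovery then checks the full pipeline: 10 seeded noisy control movies
must return all seven layer radii within one lateral pixel and the four
onset means within half a frame; 20 *gpr-1/2* movies must yield no rupture
or packets in ≥95 % of seeds; *csnk-1* movies must rupture earlier than
control.  Problem sizes (10–20 movies of 12–16 frames on a
96×128×24 grid) keep the whole suite at desk scale — a few minutes on one
CPU — while leaving every detector operating far from its noise floor.

## Known limitations

* The hole detector assumes an approximately stable pre-rupture mask; very
  fast whole-structure collapse would be attributed to the volume-drop
  branch (the two onsets are reported separately for exactly this case).
* The inner-scaffold volume series triggers the generic volume-drop
  detector during normal shrink; rupture semantics are only meaningful for
  outer-sphere channels, as in the original analysis.
* Absolute intensities are arbitrary camera units; only ratios, shapes and
  times are comparable across conditions.
* Sub-pixel boundary recovery is biased low by roughly 2 % (half-level
  inflation by noise on the profile maximum), well inside the one-pixel
  acceptance band.
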