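# Methods

This note records the models implemented in `nervect`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical conventions that matter for reproducing results.

## Scales, axes and formats

All grey values are handled on a normalized [0, 1] scale; integer stacks
are divided by their dtype maximum at the I/O boundary (65535 for 16-bit
TIFF), so every metric is computed in the same units in which staining
contrast is conventionally reported. Arrays are indexed `(z, y, x)` with
XY the nerve cross-section and z the nerve's long axis; voxels are
isotropic with a default edge of 4 μm, and physical positions are
`index × voxel_size_um` at voxel centres. NIfTI files store the voxel
size in mm (μm × 10⁻³) under an identity-orientation affine and float32
grey, so a round trip is exact to float32 precision — well inside the
1/65535 quantization of the TIFF path. No scanner geometry is encoded.

## Contrast metrics

**Distinguishability.** `d` is the sum of pairwise absolute differences
of the mean greys of fascicle, interfascicular epineurium and adipocyte
tissue. For any three reals this equals twice their range,
`2·(max − min)`, which the test suite asserts on random triples; `d` is
permutation-invariant, non-negative, zero iff the three means coincide,
invariant under a common additive shift and linear under a common
non-negative scale. Means are arithmetic means of member pixels; the
spread reported alongside repeated measurements is the standard
deviation over repeated profile lines (at least three), a repeat-line
spread rather than a per-pixel one.

**SNR.** Mean grey of a fascicle pixel block divided by the standard
deviation (population form) of a background block. Blocks are
axis-aligned boxes supplied explicitly or drawn within labelled regions;
they must not overlap, and a zero-variance background is rejected rather
than reported as infinite. The ratio is invariant under multiplicative
intensity scaling.

**Line profiles** are sampled at unit-pixel steps along the segment by
bilinear interpolation, so a 100-pixel segment yields 101 samples; the
exact resampling used by interactive tools varies, and unit-step
bilinear sampling is the simplest reproducible choice.

**Ranking** returns the condition with the maximal score; ties break to
the earliest listed condition and are flagged.

## Conditioning chain

The canonical order is trim → stretch → median → longitudinal smooth →
binarize. Choices where the workflow left room:

* Trim counts are configurable; a default of 2% of the stack per end is
  reasonable for cone-beam end artefacts at desk scale.
* Histogram stretching maps the (0.5, 99.5) percentile band onto [0, 1]
  and clips outside — enough to discard stray extreme pixels without
  compressing tissue contrast.
* The 3×3×3 median and the 1×1×5 longitudinal kernel use reflect
  padding; the longitudinal kernel is uniform (1/5 each). Both filters
  are verified against brute-force oracles (sort-and-pick; explicit
  5-term sum).
* Binarization is a closed two-sided interval `[low, high]`, matching
  the idea of a grey *band* occupied by fascicles rather than a single
  cut.
* `suggest_threshold` partitions the histogram by multi-level Otsu and
  picks the class nearest a fascicle-mean hint, then refines it by
  further two-level splits while a sub-class moves the class mean closer
  to the hint. The refinement matters because the count-weighted Otsu
  optimum can lump a minority tissue (cling film) in with fascicles. The
  result is a suggestion and is always overridable: the original
  workflow set this threshold manually per scan.

## Segmentation and tracking

Region growing is the neighbourhood-connected filter: all voxels whose
grey lies in the active range and that are connected to a seed through
in-range voxels. Default connectivity is 26-neighbour in 3D, with
8-neighbour connectivity for per-slice cross-sections; the output is by
construction a subset of the thresholded volume and every component
contains a seed. Mask smoothing is morphological closing with a ball
element, implemented with the dilate-border-0 / erode-border-1
convention so that closing is idempotent and does not erode structures
touching the volume faces.

Tracks are built by footprint overlap between consecutive slices (at
least one shared (y, x) voxel) — robust to the in-plane wobble of real
fascicles at 4 μm voxels, where centroid-distance linking can jump
between neighbours. Link patterns map to events:

* 1→n: **BRANCH** (children recorded as new tracks with lineage).
* n→1 followed by a re-split within the plexus window: **PLEXUS** on all
  participants; the merge and re-split are consumed by the event.
* n→1 with no re-split in the window: **BOUNDARY_GAIN** candidate.
* Disappearance before the last slice: **BOUNDARY_LOSS** candidate.

**Boundary loss** is confirmed when, at a z-transition, more than half
of the previous footprint has no in-mask continuation. The "more than
half of the diameter" phrasing is operationalised as a footprint
fraction because a diameter-wise chord is ill-defined for irregular
cross-sections; the in-plane-contour alternative reading is noted but
not implemented.

**Boundary gain** is confirmed for any merged component carrying two or
more fascicle identities unless a plexus — declared in an annotation or
observed as a PLEXUS event — lies within 3 mm along z of the merge
("within 3 mm of nerve" is taken as axial distance; at 4 μm voxels the
window is 750 slices). When reference tissue labels are available, a
track whose footprint is more than 10% adipocyte or epineurium voxels is
also flagged; the 10% tolerance absorbs boundary voxels flipped by
smoothing.

**Acceptability.** A tracing is acceptable iff the number of founding
tracks whose lineage (through branches and plexuses) spans the full
retained z-range reaches the configured minimum — three or more
fascicles for a rat sciatic nerve, ten for a pig vagus nerve — and no
boundary loss or gain is confirmed. BRANCH and PLEXUS events are
anatomy, not defects, and never disqualify.

The original workflow is semi-automatic (seeds and thresholds chosen
interactively); here both come from configuration so that runs are
reproducible.

## Validation

Per-slice regions are 8-connected components; area is voxel count times
voxel area and the equivalent diameter is that of the circle of equal
area, `2·sqrt(A/π)` — a single-number diameter for possibly
non-circular fascicles. Percentage differences are taken relative to the
reference (histology or phantom truth), which is asymmetric; a
symmetric mean-denominator variant is available by flag. Volumetric
agreement with ground truth is scored with the Dice coefficient.

## The synthetic phantom

The generator emulates a stained nerve wrapped in cling film on sponge:
a cylindrical epineurium (radius 0.38 × the smaller cross-sectional
extent by default), fascicle tubes inside it, an 8 μm film shell,
adipocyte spheres hugging the film, and sponge/air elsewhere. Default
grey means are fascicle 0.55, epineurium 0.75, adipocyte 0.92, cling
film 0.30, sponge/air 0.18 — adipocyte and sponge/air anchored to
reported stained-nerve values, the others chosen to reproduce the
characteristic ordering (fascicles darker than epineurium, both between
sponge/air and adipocytes) — with per-tissue Gaussian texture plus a
global additive Gaussian noise term, clipped to [0, 1]. Gaussian noise
was chosen for the analyzability of the SNR properties, not as a physics
model.

Fascicle centrelines are a base offset plus a circular sinusoidal
wobble. A **branch** ends the parent tube at the declared z and glides
two children from the parent's position onto their own paths with a
sublinear ramp, so the pair separates within a few slices. A **plexus**
blends two tubes onto their midpoint where they share one lumen of
radius `hypot(r_a, r_b)` for a configurable run (default 200 μm), then
re-separates; partial fusion is out of scope. Ground-truth instance
labels are unique per voxel (the shared lumen is split by the bisector
of the approach direction so both participants keep positive area every
slice), while the truth *tracks* carry each fascicle's full geometric
footprint including the shared lumen — the natural reference for
overlap scoring. Truth event positions are recorded where the
rasterized geometry actually merges or separates, since that is what
slice-linking can observe. Undeclared tube overlaps and tubes leaving
the epineurium are rejected with diagnostics. Identical spec and seed
give bit-identical volumes.

**Movement artefact** is a contiguous run of `ceil(fraction × nz)`
slices, each rigidly translated in-plane by a random integer offset up
to the configured maximum, vacated voxels filled with the sponge/air
mean — rigid integer shifts only, no rotation or deformation.

**Staining-time model.** No quantitative staining-day → grey-value
relationship is available, so protocol-recovery experiments use a
synthetic response surface: a gamma-like unimodal factor
`g(day) = (day/opt)·exp(1 − day/opt)` drives the three soft-tissue means
apart from a common unstained baseline (fascicle 0.62 − 0.07 g,
epineurium 0.65 + 0.10 g, adipocyte 0.66 + 0.26 g), peaking at the
profile's optimum day (rat profile: day 1; pig profile: day 5) where the
means equal the phantom defaults, and relaxing toward the baseline
plateau under over-staining. Its parameters are modelling choices, not
measurements.

**What the phantom does not emulate:** beam hardening, cone-beam
projection geometry, ring artefacts, iodine diffusion kinetics, partial
fascicle fusion, non-rigid motion, and intensity drift along z. Passing
recovery tests on phantoms therefore demonstrates the correctness and
internal consistency of the algorithms under known geometry and noise —
not performance on real scans, where thresholds in particular required
per-scan adjustment in practice.

## Problem sizes and determinism

Desk-scale defaults keep every experiment reproducible on a laptop: the
standard evaluation phantom is 112×112×240 voxels at 4 μm (≈0.45 × 0.45
× 0.96 mm) with four founding fascicles, one branch and one plexus;
staining-day experiments use 64×64×12 phantoms per day, where a few
thousand voxels per tissue estimate the class means far more precisely
than the day-to-day contrast differences being ranked; oracle-agreement
checks use random volumes up to 32³. Real scan volumes are orders of
magnitude larger; every size is configurable. All stochastic steps take
explicit integer seeds, and the acceptance script derives every seed
from its `--seed` argument.

## Known limitations

* Tracking links by footprint overlap only; fascicles that slide more
  than their own width between consecutive slices (coarse z sampling or
  strong motion) would need the centroid-linking alternative.
* The boundary-gain tissue-contamination check needs reference labels
  and is therefore phantom-/annotation-only.
* The plexus window compares axial distance, not geodesic distance along
  the nerve; for strongly curved nerves these differ.
* `suggest_threshold` assumes the fascicle grey band is unimodal and
  separated; bimodal staining within fascicles would defeat the hint
  refinement.
* Many-to-many slice transitions (simultaneous merge and split in one
  step) are resolved greedily by maximal overlap.
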