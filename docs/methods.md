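# Methods

`cristaseg` quantifies inner-mitochondrial-membrane ultrastructure —
cristae — in live-cell super-resolution fluorescence micrographs. This note
describes the models and procedures the package implements, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Pipeline overview

A frame passes through seven stages:

1. **Background subtraction** (rolling ball, radius 50 px by default).
2. **Feature stack**: raw intensity, Gaussian blur and Sobel gradient
   magnitude at sigmas {1, 2, 4, 8, 16} px, and six membrane-projection
   statistics — 17 planes per pixel.
3. **Pixel classification**: a random forest trained on sparse user strokes
   labelled *Cristae* vs *Background* emits a per-pixel probability map.
4. **Thresholding** of the cristae probability plane (default 0.5) into a
   binary mask.
5. **Particle extraction**: 8-connected components, excluding particles
   below the theoretical crista cross-section of 0.017 µm² (boundary
   inclusive).
6. **Morphometry**: calibrated area, perimeter, circularity
   (4π·area/perimeter², capped at 1), and moments-ellipse aspect ratio;
   cristae density = count per µm² of mitochondrial-network area, the
   network being segmented separately.
7. **Time-lapse** (optional): organelle tracking by overlap, per-track
   metric traces, and SD-per-minute dynamic ranges.

## Background subtraction

The rolling-ball background is the grayscale opening of the intensity
surface with a spherical-cap structuring element: the highest surface a
ball of the stated radius can reach while staying under the image. It is
computed exactly (no image-shrinking speedup) on a reflect-padded copy (pad
= 2× radius) so no boundary extension leaks into the estimate. Intensities
are processed in floating point; 16-bit counts are not rescaled.

Two properties of the classic algorithm are worth knowing. First, the ball
is a 3-D object whose vertical extent is measured in intensity units, so
its stiffness depends on the intensity scale: at 16-bit detector scale the
filter is nearly idempotent, while on images whose full range is only a few
hundred counts a radius-50 ball can ride partway up wide organelles on a
second pass. Second, a single-pixel spike is preserved only up to the cap's
sag between pixels (√(r²−1) − r counts), not exactly.

## Feature stack

The three feature families are the ones a trainable-segmentation user
enables for membranous structures. Parameters are the public defaults of
that workflow: Gaussian/Sobel sigmas {1, 2, 4, 8, 16} px, membrane kernel
19×19 px with a 1-px line rotated through 30 orientations at 6° steps,
rasterized by nearest-neighbour inclusion (a pixel is on the line when its
perpendicular distance is ≤ width/2). Each oriented kernel is normalized to
unit sum — rasterized lines have orientation-dependent pixel counts, and
normalization makes the response to a flat field identical across
orientations (so the membrane-std plane is exactly zero there). Features
are computed in pixel units; µm calibration enters only at measurement
time, so a classifier ports across images with equal pixel size. Raw
intensity is included by default and configurable.

## Pixel classifier

A scikit-learn random forest with 200 trees, ⌊√d⌋ features per split and a
fixed seed (42). Probabilities are the mean of per-tree leaf posteriors,
which gives smoother maps than hard-vote fractions and behaves better under
the 0.5 threshold. Out-of-bag stroke accuracy is logged after every
training session; there is no automatic stopping rule — the annotate/train
loop stops when the user is satisfied. Training data can be accumulated
across images and sessions, and imported/exported as ARFF so published
training sets can be reused. The class order (Cristae, Background) is fixed
everywhere; the cristae plane is channel 0.

The reference training recipe used throughout the tests samples 400 stroke
pixels per class from ground-truth masks of two independent synthetic
scenes, keeping strokes at least 1 px away from class boundaries (an
annotator does not trace ambiguous pixels). Sampling background strokes
from both the mitochondrial matrix — including the narrow gaps between
adjacent cristae — and the extracellular background is essential: without
gap examples the forest labels entire organelle interiors as cristae.

## Histogram thresholding baselines

MaxEntropy (Kapur–Sahoo–Wong: maximize the sum of background and foreground
Shannon entropies) and Shanbhag (minimize the absolute fuzzy-membership
information difference) are implemented directly on 256-bin histograms,
evaluated exhaustively over all candidate bins; Otsu and iterative isodata
share the same path. Images are min–max scaled to 256 bins (8-bit
emulation) before histogramming, and bins strictly above the selected bin
are foreground — both conventions match the reference implementations of
these criteria. Near-degenerate cases where two bins' criterion values
differ only by summation round-off (~1e-16) are genuine floating-point
ties; tests accept either bin.

## Morphometry conventions

* **Perimeter**: the outer boundary is the marching-squares contour of the
  particle mask, simplified by Douglas–Peucker with a 1.0-px tolerance
  before measuring polygon length. Raw chain-code length overestimates
  smooth outlines by ~5% and crack (Manhattan) length by much more; the
  simplified-contour estimator converges for both polygonal and smooth
  shapes — large digital disks measure circularity 0.996 and digital
  squares 0.789 vs the ideal π/4 = 0.785. For particles so small that
  simplification collapses the polygon, the unsimplified contour length is
  used.
* **Circularity** is capped at 1.0: tiny particles can rasterize above 1,
  and the cap is what makes the textbook value of exactly 1 attainable for
  a round fragment.
* **Ellipse / aspect ratio**: second-order central moments with the 1/12
  per-pixel variance of a unit square added, making the estimate exact for
  axis-aligned rectangles (a 240×20 raster gives AR 12.000) and
  non-degenerate for single-pixel and collinear sets (AR 1 for a single
  pixel). Axes are scaled so the ellipse preserves the particle's area.
* **Single pixel**: area s², perimeter 4s, circularity 1, aspect ratio 1.
* **Assignment**: particles belong to the mitochondrion containing their
  centroid; particles whose centroid lies outside every organelle are
  dropped with a logged count.
* **Cristae per mitochondrion** is the mean over per-organelle counts, not
  the ratio of totals; the per-cell density denominator is the
  mitochondrial-network mask area.
* **Experiment aggregation** is two-level: unweighted cell means per
  experiment, then mean ± SD over experiment means (SD undefined for a
  single experiment).

## Mitochondrial network segmentation

The density denominator needs a whole-organelle mask. The default strategy
smooths with a Gaussian of sigma 2 px and applies Otsu. Sigma 2 was chosen
after measuring mask quality against ground truth: sigma 4 dilates the
network by ~25% in area (Jaccard 0.85), which alone would dominate the
error budget of density measurements, while sigma 2 gives Jaccard ≈ 0.96
and ≈ +5% area. A classifier-based strategy (a second two-class model
trained on organelle-vs-background strokes) is available for images where
intensity thresholding fails.

## Time-lapse dynamics

Organelles move little between ~2-s frames, so linking is greedy
maximum-overlap: candidate links between consecutive frames are accepted
one-to-one in descending IoU order, admissible above IoU 0.1. Remaining
overlaps record fission (one→two) and fusion (two→one) events; organelles
with no admissible overlap start or end tracks.

"SD per minute" is defined here as the sample SD of a per-track metric
trace multiplied by (60 s / window duration), i.e. linearly normalized to a
one-minute observation window; the window is last minus first sample time.
This convention is declared (not derived), configurable back to plain
windowed SD, and named `sd_per_min_linear` in all output headers. Frames
where an organelle has zero cristae contribute density 0 and count 0 but
missing shape means, which are excluded pairwise per metric. Traces need at
least 3 non-missing samples spanning ≥ 10 s. Exactly constant traces report
exactly 0 (guarded against floating-point round-off of the mean).

## Synthetic scene generator

The generator emulates live-cell Airyscan/SIM imaging of membrane-dye-
stained mitochondria; it is the package's validation instrument, with full
ground truth. Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.04 µm | SIM/Airyscan sampling |
| PSF sigma | 0.0425 µm | ~100 nm FWHM lateral resolution |
| crista width | 0.02 µm | electron-tomography scale |
| crista spacing | 0.25 µm | countable-lamellae regime (see below) |
| contrast cristae:matrix:background | 3 : 1 : 0.1 | membrane-dye staining |
| photon scale | 200 counts per unit | shot-noise-limited SNR ≈ 15 |
| read noise | 2 counts RMS | sCMOS-like |
| supersampling | 4× | sub-pixel rasterization |

Organelle bodies (tubes, ouroboros rings, fragments, intermediates) are
placed on a jittered grid (collision-free by construction) and filled with
lamellar, arched, jigsaw, radial or vesicular cristae. Scenes are
rasterized at 4× supersampling in world coordinates, blurred with the
Gaussian PSF, block-averaged to the detector grid, then degraded with
Poisson and Gaussian read noise. Everything derives from the scene seed.

The default spacing of 0.25 µm represents the *countable* subpopulation of
cristae: the apparent (post-PSF) lamella width is ~3 px, so discrete
counting requires roughly one PSF FWHM of clear gap between neighbours.
Electron microscopy reports inter-crista distances down to ~50 nm; those
regimes are emulated by lowering the spacing (0.18 µm for the
baseline-comparison fixture, 0.08 µm for the unresolvable regime) and are
exactly where counting degrades — by design, since that degradation is the
phenomenon under study. True 20-nm crista width also means the measured
(PSF-inflated) crista area exceeds the true area by a factor of ~5–10; the
generator reproduces this overestimation as an emergent property, not a
hard-coded factor.

Quantization: at 4× supersampling a 2-subpixel-wide bar's true area
quantizes within ~8% per crista (~1% on average); doubling the
supersampling halves it.

Perturbation presets modify the study conditions in the directions the
package is meant to detect: `ptpmt1_like` (cardiolipin-deficiency-like
swelling) widens cristae five-fold and doubles their spacing — density
down, area up, aspect ratio down; `fccp_like` (uncoupler-like remodeling)
replaces lamellae with small vesicular rings (radius 0.045 µm) at wider
spacing — density down, area down, circularity up. Directions hold both in
the ground truth (by construction) and through the full measurement
pipeline (verified by tests).

Scripted time-lapse events: cristae fusion (two adjacent lamellae → one
arch), cristae fission (lamella → two vesicular fragments), whole-organelle
fission (pinch with local cristae loss at the site) and fusion (merged
body). Positional Brownian jitter is optional. The deterministic signal is
identical across frames when no events and no jitter are scripted; noise
realizations are drawn independently per frame.

**What the generator does not emulate**: vectorial/structured-illumination
PSFs and reconstruction artefacts, 3-D geometry (single plane only), dye
photochemistry and bleaching, organelle deformation beyond rigid jitter,
and the dense sub-resolution cristae packing of real matrix-rich regions.
Passing tests therefore demonstrate correctness of the measurement chain
and the direction/order-of-magnitude of resolution-induced biases, not
performance on any particular real microscope's data.

## Problem sizes

Validation uses 256×256 frames (10.24 µm field) with 4 organelles and
~30–50 cristae, classifiers with 200 trees trained on 1,600 stroke pixels,
and 16-frame traces at 2-s intervals; these sizes keep every property
measurable while the full suite runs on a laptop-class machine.

## Known limitations

* Counting accuracy collapses below ~0.2 µm spacing at 40-nm pixels — an
  imaging-physics limit the package measures rather than overcomes; no
  watershed splitting of merged particles is attempted.
* The manual baseline requires a user-chosen intensity threshold; the
  comparison harness has no automatic surrogate for human judgement.
* Tracking is overlap-based and will fragment tracks of organelles that
  move more than their own width per frame.
* Event classification is lineage-derived (from track topology) or
  user-marked; sub-organelle (per-crista) tracking is out of scope.
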