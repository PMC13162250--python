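# Methods

`filasense` is a self-contained synthetic re-creation of a laser-filament
particle-sensing experiment: airborne particles (chalk dust, pollen grains,
salt crystals) crossing a femtosecond laser filament produce optical emission
events that a side-mounted RGB camera records; a CNN classifies single frames
into {blank, chalk, pollen, salt}, and auxiliary analyses characterise the
physics (spectral broadening onset, intensity clamping), the colour structure
the network exploits (Grad-CAM chromaticity clusters), and the particle
morphology (dark-field slide metrology).  Everything runs from parametric
generators; no external data is required.

## The scene generator and what it emulates

A frame is 1920x1200 RGB: Gaussian sensor noise (sd 1.2 counts on a
background of 16 — the ratio controls how tightly background and stripe
pixels cluster in chromaticity), a horizontal near-neutral filament stripe
(Gaussian vertical profile, fwhm 12 px, length 1400 px — the image of a
~3 mm channel), and a Poisson
number of emission events with class means 5 (chalk), 1 (pollen), 3 (salt)
and 0 (blank).  Each event is an isotropic 2-D Gaussian blob (sigma
truncated-normal 16 +- 3 px in [9, 26]) placed along the stripe; its colour
is obtained by drawing a class emission spectrum (line amplitudes jittered
log-normally, sd 0.2 in log space) and integrating it against parametric
Gaussian camera responses centred at 600/540/460 nm (fwhm 80 nm) for R/G/B.

Class spectra follow the underlying emission physics in line *positions* —
Ca II 393.4/396.9 nm, Ca I 422.7 nm and a green Ca I multiplet near 554 nm
plus CaO orange band heads near 603–650 nm for chalk; the Na D doublet at
589.0/589.6 nm for salt; a broad organic-fluorophore band centred at 525 nm
(fwhm 60 nm) for pollen; a weak blue-ish continuum for the bare filament —
while the *amplitudes* are artifact parameters calibrated once so that the
rendered chromaticities fall in distinct regions: chalk warm pink
(r≈0.63, g≈0.26, with the blue fraction 0.12 separating it from salt),
pollen green (r≈0.14, g≈0.64), salt orange (r≈0.70, g≈0.30, almost no
blue), blank near neutral (1/3, 1/3).  Under these defaults the closest
chromaticity pair — in pooled-covariance Mahalanobis distance, as measured
by the analysis itself — is chalk–salt, and blank is by far the most
distinct cluster, mirroring the qualitative cluster structure of real
filament emission data.

The stripe peak (60 counts) is deliberately a factor ~4 below the event
peak (235 counts): the brightest-pixel chromaticity analysis must see
event colour, not stripe colour, in non-blank patches even after the
960 -> 128 downscale dilutes small blobs.  For scaled-down profiles the
saliency patch side scales with the input (input/8, i.e. 64 px at 512 and
16 px at 128) so a patch covers the same image fraction as in the full
geometry; a fixed 64-px patch at 128 input would span half the frame and
drown event colour in stripe pixels.

What the generator does *not* emulate: ablation/fragmentation dynamics,
event shape anisotropy, motion blur, frame-to-frame correlation within a
video, sensor saturation structure, or any overlap between class colour
distributions beyond the log-normal jitter.  Classification on this material
is therefore substantially easier than on real camera data, and the
end-to-end accuracies the tests assert demonstrate that the pipeline is
correct and well-conditioned — not that the architecture would reach these
numbers on real frames.

### Dataset bookkeeping

Each frame is cropped into two 960x960 segments (vertically centred, rows
[120, 1080)); the curated dataset counts *segments*: 71 blank, 59 chalk, 63
pollen, 33 salt (226 total), split stratified into 180 train / 46 validation,
plus 26 held-out test segments (8/7/7/4 per class, chosen proportional to
the curated counts) and a 107-segment robustness set (25/28/27/27) rendered
at power fraction 0.85.  Curation means a non-blank segment must contain at
least one emission event; frames are rendered until each quota is met.
Per-frame seeds derive from the master seed, so a manifest is reproducible
byte-for-byte.

## Power-dependent spectral model

The clamping model is phenomenological.  The emitted intensity scale is
linear in power fraction p below the onset p0 = 0.85 and saturates
exponentially above it (width 0.05), so it is strictly increasing, C1, and
approaches the plateau p0 + 0.05 — intensity clamping.  Spectral broadening
is a one-sided Gaussian wing above 550 nm whose width jumps from 18 nm to
63 nm at onset and grows at 160 nm per unit power thereafter; the
discontinuity makes the onset grid point itself detectable, matching the
step-like appearance of supercontinuum once full filamentation is reached.

The onset detector computes the supra-550 nm fraction of the trapezoid-
integrated spectrum at each power, takes the three lowest powers as a
baseline, and reports the smallest power exceeding baseline mean + 3 sd
(with a 1e-9 absolute guard so that noise-free series with identical
baseline fractions do not trigger on float jitter).  On a 20–100% grid in
5% steps it recovers p0 exactly for noise-free input.

Peak intensity uses one documented convention: Gaussian temporal peak power
P = 0.94 E/tau, diffraction-limited waist w0 = 2 lambda f / (pi D) for an
input 1/e^2 beam diameter D, and on-axis intensity I = 2P/(pi w0^2).  At
1.0 mJ / 190 fs / 1030 nm / f = 100 mm / D = 8.9 mm this gives
5.802e15 W/cm^2.  Only linearity in E and the 5.0x ratio across the
0.2–1.0 mJ energy range are asserted as physics; the absolute value is kept
as a frozen regression constant because no standard convention reproduces
the ~1e14 W/cm^2 scale quoted in the experimental literature for these
parameters.

## Preprocessing and augmentation

Resizing is centre-aligned bilinear interpolation (output pixel i samples
input coordinate (i+0.5)·in/out − 0.5, edges clamped) with a Gaussian
anti-alias prefilter of sigma (ratio−1)/2 per axis when downscaling, so that
few-pixel emission blobs survive the 960 -> 128 reduction.  Augmentation
applies, in this order: random x/y reflection (p = 0.5 each), rotation
uniform in +-5 degrees, per-axis scaling uniform in [0.95, 1.05], and vertical
translation uniform in +-height/8 (horizontal translation is disabled — a
large x-shift could push emission events out of the segment).  All
transforms compose into a single affine warp about the image centre with
bilinear sampling and reflect border fill.

## The classifier

Four convolutional blocks of 3x3/stride-1/same convolutions, each conv
followed by batch normalisation and ReLU: blocks 1–3 have two convs (32, 64,
128 filters) and end in 2x2/stride-2 max pooling; block 4 is a single
256-filter conv.  The head is flatten -> dropout 0.5 -> 128-unit ReLU dense
layer -> 4-way dense -> softmax.  At the full 512x512 input the spatial
sides run 512/256/128/64 through the pools.  Inputs are RGB in [0, 1]; no
mean subtraction.  Weights are seeded uniform fan-in draws.

Training: Adam (beta 0.9/0.999), initial learning rate 1e-4 multiplied by
0.1 every 30 epochs, minibatch 8, shuffling each epoch, categorical
cross-entropy, validation every 100 iterations, 60 epochs; the checkpoint
with the best validation accuracy is kept (no early stopping).  The
**small profile** — used by the entire test suite and the acceptance script
— keeps every training hyperparameter but runs 30 epochs at 128x128 input
with filters halved (16/32/64/128); one desk-scale run takes a few
minutes on a single CPU core.

The network and its backpropagation are implemented directly on NumPy
(`filasense.nn`): NHWC float32 tensors, convolutions as row-decomposed
im2col + BLAS GEMM for both passes, exact batch-norm backward, argmax-routed
pooling gradients, inverted dropout.  A finite-difference test validates the
gradients end to end.  Three forward modes exist: train (batch statistics,
dropout on), eval (running statistics, no caches), and grad (inference
semantics with caches — used by Grad-CAM, where the batch-norm backward is
the affine per-channel form because the running statistics are constants).

## Grad-CAM and chromaticity clusters

Saliency taps the second ReLU of the third convolutional block.  The
heatmap is ReLU(sum_c alpha_c A_c) with alpha_c the spatial mean of the
target-class pre-softmax score gradient at that layer, bilinearly upsampled
to the input and max-normalised.  For each correctly classified test image
the three most intense non-overlapping 64x64 windows are taken greedily
(row-major first on argmax ties; windows re-centred inside the frame at
borders), the 30 brightest pixels per window selected by R+G+B, and each
mapped to (r, g) = (R, G)/(R+G+B).

Cluster separation: per-point silhouettes with Euclidean distance in (r, g);
per-class mean/median/IQR/fraction-positive/n; the weighted mean over
classes (equal to the global mean) with a normal-approximation 95% CI using
the pooled standard deviation.  Centroid separation: Mahalanobis distance
with the pooled within-class covariance (N−k denominator), ridge-regularised
at 1e-8·tr(S)/2 if ill-conditioned.

## Morphology

Dark-field slides show bright particles on a dark background.  The
generator draws equivalent diameters from per-class truncated normals
(chalk 9.4 +- 4.1 um in [3, 28]; pollen 20.7 +- 3.8 um in [4.6, 30.7]; salt
21.8 +- 6.8 um in [12, 37]) at 0.192 um/px, and shapes as rough ellipses:
the base ellipse fixes the moment eccentricity (targets 0.60/0.55/0.66),
cosine boundary modes 3–9 add roughness whose amplitude is solved by
bisection so the polygon circularity 4·pi·A/P^2 matches the class target
(0.74/0.86/0.70) with sd-0.02 jitter.  Mode 2 is excluded because it would
alter the second-moment ellipse itself.  Ground truth (area, perimeter,
circularity, eccentricity) comes from exact shoelace/Green's-theorem polygon
formulas.  Size and shape are drawn once per particle and only the position
is re-drawn on overlap, so crowding cannot bias the size distribution.

Segmentation is Otsu global thresholding, 8-connected labelling, and
per-region shape metrics; rows below 3 um equivalent diameter are dropped.
The circularity perimeter is the length of the marching-squares contour
after moving-average smoothing with an adaptive window (contour length / 24,
clamped to [3, 9] samples): raw pixel-edge counting overestimates smooth
perimeters by the staircase factor, while an oversized window erases genuine
boundary roughness of the smallest particles.  Validated limits: a large
rasterized disc measures C within ~1% of 1, a 100-px square within 0.03 of
pi/4, a 2:1 ellipse within 0.005 of its Ramanujan value.

Air-sampler bookkeeping is direct arithmetic: V = Q·t/1000 (10 L/min x
9 min = 0.09 m^3), concentration N/V, surface density N/area.  342/0.09 =
3800 m^-3; the ~3.4e3 m^-3 sometimes quoted for these numbers is not
reproducible by this quotient and is reported as a flagged discrepancy, as
is the reduced-power mean accuracy (the four per-class values 93.5, 96.4,
70.4, 97.2 average to 89.4, not 88.9).

## Numerical and design choices

* All randomness flows through `numpy.random.Generator` seeded per stage
  from a master seed via a fixed SeedSequence spawn order; reports are
  reproducible bit-for-bit.
* Max-pool gradient ties route to the first maximum; patch-selection
  argmax ties are row-major first; both documented tie-breaks are tested.
* The supra-550 integral interpolates the spectrum at exactly 550 nm when
  the cut falls between grid samples, keeping band fractions exact on any
  grid.
* Power-fraction validation tolerates 1 ulp of accumulation error so grids
  built with `arange` do not trip the (0, 1] contract, and the broadening
  law treats p within 1e-9 of the onset as at-onset.
* Training calls a best-effort glibc `mallopt` tune to retain large freed
  buffers: the im2col workspaces are re-allocated every step and round-trip
  through mmap otherwise, doubling step time on one CPU.
* Problem sizes in the test suite: the acceptance-level run uses the small
  profile at the study's full dataset counts; generator statistics tests use
  a reduced 480x300 scene (geometry scales, statistics unchanged); slide
  metrology tests use 200–500 particles at 0.192–1.0 um/px depending on the
  statistic under test.

## Known limitations

* The NumPy training loop is single-process and CPU-bound; the full profile
  (512x512, 60 epochs) is functional but slow (hours, not minutes).
* The clamping model is descriptive; it cannot predict onset position from
  pulse parameters, only embed a chosen one.
* Rough-ellipse particles cannot reproduce concave or aggregated particle
  habits; segmentation on real dark-field images would face touching
  particles, which the generator deliberately avoids.
* The camera model ignores spectral response tails and sensor nonlinearity;
  chromaticity positions therefore shift if real response curves are
  substituted.
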