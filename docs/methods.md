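# Methods

## The simulation model

The simulator emulates the live-cell experiment that motivates the package:
a cell expressing a nuclear F-actin chromobody and a calcium sensor, imaged
every few seconds around a calcium-mobilizing stimulus.

**Geometry.** The nucleus is a 2-D disc, default diameter 10 µm, embedded in
a pixel grid (default 0.1 µm pixels, 120×120 image). Physical coordinates
are micrometres with the origin at the centre of the top-left pixel; a pixel
belongs to the nucleus when its centre lies in the disc. Real nuclei are 3-D
and non-circular; the disc keeps the variance statistic interpretable and is
the geometry under which the proxy validation is stated.

**Filament kinetics.** Nucleation is a homogeneous Poisson process with mean
inter-arrival 20 s that switches on a fixed latency of 16 s after the
stimulus — the observed delay between ionophore addition and the first
polymerization. Each filament receives an origin (uniform in the disc by
default; an `inm_anchored` mode places origins on the boundary with inward
directions, matching filaments elongating from the inner nuclear membrane),
a uniform direction, and an exponential lifetime with mean 50 s. Filaments
elongate at 1.5 µm/s, clamp when the tip reaches the boundary, and vanish
instantaneously at end-of-life (no shrink phase is modelled; the experiments
report depolymerization within a minute but no kinetics). The two origin
conventions are both offered because the live-cell data show membrane-
anchored filaments while the validation simulation nucleates throughout the
nucleoplasm; no single intent can be reconstructed, so neither is guessed.

**Rendering.** Expected intensity = homogeneous background (default
100 photons/pixel) inside the nucleus, zero outside, plus each filament's
line contribution: `gain × length` photons (default 2000 photons/µm)
deposited along the segment with bilinear sub-pixel weighting and convolved
with an isotropic Gaussian PSF (σ = 0.2 µm). With `noise="poisson"` every
pixel is an independent Poisson draw of its expectation — the shot-noise
limit, which makes the pre-stimulus spatial variance equal the mean photon
count (Fano factor 1). Rendering is additive rather than mass-conserving:
polymerization concentrates probe without changing the total by much, the
variance statistic responds identically either way, and an optional
`conserve_total` flag redistributes filament photons out of the background
for users who prefer strict conservation. The gain is chosen so a single
filament raises the ROI variance well clear of the shot-noise floor
(a bright chromobody-labelled bundle); background and gain are expected
photon counts, not camera units.

**Calcium channel.** A phenomenological difference of exponentials
`A·(e^(−t/τ_decay) − e^(−t/τ_rise))`, scaled to peak amplitude (defaults:
baseline 50, amplitude 150, τ_rise 2 s, τ_decay 15 s), with the nuclear
compartment delayed 1 s behind the cytoplasm. The experiments measure the
transient but do not parameterize it; these values reproduce a fast rise and
sub-minute decay typical of ionophore/thapsigargin responses. The calcium
frame renders the nuclear value inside the disc and the cytoplasmic value
outside, so both compartment ROIs can be read from one image.

**Acquisition defaults.** Frame interval 3 s (the acquisitions ran every
2–4 s), total duration 240 s with the stimulus at 60 s. The four-minute
window matches the several-minute live-cell movies and gives a 20-frame
pre-stimulus baseline; events later than ~180 s after latency are so rare
(P < 10⁻³) that censoring is negligible.

**Randomness.** One `numpy` generator per simulation, seeded from the
config; populations derive independent per-cell sub-seeds from a population
seed. Identical configs and seeds give bit-identical stacks.

## The NAA statistic and scoring

The heterogeneity of the actin-probe channel is its **spatial intensity
variance** over the nuclear ROI, population convention (divide by N): it is
a descriptive statistic of the full pixel set, not a sample estimate. Traces
are min–max normalized by their changing range; a zero-range trace (flat
non-responder) normalizes to zeros with a `degenerate` flag instead of
raising, because such traces are expected inputs.

A cell is called NAA-positive when its post-stimulus peak raw variance
exceeds `baseline_mean + k·baseline_sd`, with the baseline taken over all
frames strictly before the stimulus and k = 5 by default. The underlying
experiments scored positivity by eye ("structures could be detected"), so
the rule here is declared, parameterized and exposed rather than inferred.
The decision is invariant to rescaling a given trace (peak, mean and SD
scale together) but not to changing the optical gain before re-imaging,
since Poisson noise does not rescale linearly; the empirical operating
characteristics under the default conditions are ~100% power on responders
and a false-positive rate well under 5% on non-responders (both checked in
the test suite).

## Temporal ordering

Onset = first crossing of a threshold (default 0.5) on the normalized trace
that stays above threshold for `sustain_frames` (default 2) consecutive
frames, with the crossing time linearly interpolated between the bracketing
frames. The lag is `onset(NAA) − onset(nuclear calcium)`; positive lag means
NAA follows calcium. The claim being tested is one of order, not of absolute
latency, so a robust, parameter-light rule is preferable to model fitting;
the estimator is exactly equivariant under whole-frame shifts and onset is
monotone non-decreasing in the threshold.

## Proxy validation

The purpose of the simulation is to establish that the variance statistic
reflects the amount of nuclear F-actin. `validate_heterogeneity_proxy`
computes the Spearman rank correlation between ground-truth total filament
length per frame and the heterogeneity trace. For a fixed filament set
rendered noise-free, variance is strictly monotone in filament mass and the
correlation is exactly 1. With several stochastic filaments the variance
also depends weakly on how the mass is partitioned — filaments hugging the
boundary lose part of their PSF-blurred signal outside the ROI, and
crossings add overlap variance — so even noise-free multi-filament histories
give ρ slightly below 1 (≈0.97 under the defaults) and noisy defaults give
ρ ≈ 0.94. The exact-rank check is therefore stated on a single-filament
grow/persist/vanish history, and the stochastic regime is validated as a
median-ρ bound.

## EM heterochromatin quantification

**Generator.** An elliptical nucleus (intensity 0.56) on a lighter
background (0.78), one compact nucleolus (0.40), and dark heterochromatin
patches (0.22) occupying a requested fraction *f* of the nucleus. Patches
are the top-*f* quantile of a smoothed Gaussian random field
(scale 4 px, giving ~0.3–0.5 µm blobs at the emulated magnification) plus a
quadratic bias toward the nuclear rim, where condensed chromatin
preferentially resides. Class boundaries are softened with a 0.7 px blur and
Gaussian texture noise (σ = 0.04) is added. Ground-truth labels are
returned, with the heterochromatin count exact to the pixel.

**Segmentation.** The original workflow trained an interactive pixel
classifier on manually segmented nuclei; here the classifier is replaced by
a deterministic, annotation-free procedure. Features per pixel: raw
intensity, Gaussian-smoothed intensity at σ = 1 and 4 px, and local SD
(5×5). Features stay in native intensity units so the clusters track
electron-density levels and local SD acts as a tiebreak; z-scoring the
features instead lets the texture channel dominate and produces
boundary-artifact clusters. K-means with k = 4 runs on nuclear pixels only
(the nucleus comes from a manual mask or, failing that, an Otsu threshold;
an image with no dark/light contrast is classified entirely as background),
with centroids initialized deterministically at fixed fractions
{0.1, 0.4, 0.7, 0.95} of the robust intensity span — one seed near each
density level regardless of how unbalanced the class areas are.

Clusters map to classes by intensity order and location, never by index:
pixels outside the nucleus are background; the darkest cluster inside is
heterochromatin; the dark-intermediate cluster contributes its largest
compact connected component (solidity ≥ 0.8, ≥ 200 px) as the nucleolus,
and its remaining pixels — blurred borders between condensed patches and
nucleoplasm — are split between heterochromatin and euchromatin at the
midpoint of those clusters' mean intensities; everything else inside is
euchromatin. The reported fraction is heterochromatin pixels over all
nucleus pixels, nucleolus included (a flag excludes it); whether the
original denominator included nucleoli is not stated, so the inclusive
convention is the default and both are available.

Under the generator defaults this recovers ground-truth fractions across
f ∈ {0.1, 0.2, 0.35, 0.5} with median absolute error ≤ 0.04 and Dice ≥ 0.95
for the heterochromatin mask (checked in the test suite).

## What the synthetic data does and does not show

The generators reproduce the statistical structure the methods rely on —
Poisson shot noise, Poisson event timing, additive filament signal, distinct
EM density classes with blurred borders — but not photobleaching, focus
drift, cell movement, probe-binding chemistry, 3-D sectioning effects, or
staining variability. Passing tests therefore demonstrate that the
*algorithms* recover what they claim under their stated model, not that the
model captures every property of real microscopes; on real data the masks,
stimulus times and thresholds remain the user's responsibility.

## Numerical choices and degenerate inputs

* Variance uses 1/N; normalization of a zero-range trace flags rather than
  raises; an empty ROI mask, a missing channel, or fewer than three baseline
  frames raise `InputError`.
* Onset interpolation falls back to the frame time when the bracketing
  segment is flat or the previous frame already sits at threshold.
* Filament tip clamping solves the ray–circle intersection exactly;
  `advance_filament` is purely functional and agrees with the closed-form
  state to machine precision.
* Problem sizes in the validation suite: ≥10⁴ events for each kinetic
  recovery, 50 seeded movies for the temporal-order check, 300 + 50 cells
  for the scoring characteristics, 20 seeds per EM fraction. These give
  Monte-Carlo standard errors several times smaller than the tolerances
  they are checked against.

## Known limitations

* The variance statistic is a proxy for filament mass, not a measurement of
  it; its mapping to mass depends weakly on filament configuration (see
  proxy validation above).
* At f = 0 the EM segmenter mislabels the nucleolus as heterochromatin —
  with no truly condensed chromatin present, the darkest structure inside
  the nucleus wins. Distinguishing the two in that regime needs a shape
  prior the intensity classifier deliberately does not have.
* No nucleus auto-segmentation is attempted on real fluorescence data and
  only simple thresholding on real EM data; masks from the acquisition
  pipeline are the intended input.
* The filament model is kinematic: no bending, branching, bundling, or
  shrink-phase depolymerization.
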