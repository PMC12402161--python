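# Methods

This note documents the models and estimators `squeezelab` implements, the
choices made where several reasonable designs existed, and what the
synthetic-data tests do and do not demonstrate about real microscopy.

## Device geometry and coordinates

The modelled device is a cascade of constriction channels (CC) of strictly
decreasing width — 30, 20, 10, 5 µm by default — each 150 µm long and 15 µm
high, separated by 150 µm relaxation chambers (RC). The flow axis is the
image x axis; a baseline field of one chamber length sits upstream of the
first channel. Region intervals are contiguous and half-open; a centroid
exactly on a boundary belongs to the upstream region. Pixel indices are
0-based `(row, col)` with the origin top-left, and physical coordinates are
`index * pixel_size` (µm). The transit generator's default pixel size is
0.33 µm/px, typical of a 10x confocal acquisition sampled finely enough to
resolve a 5 µm channel.

## Squeeze model

Cells are modelled as 2-D ellipses of projected area `pi (D0/2)^2`. Inside a
channel narrower than the cell the minor axis clamps to the channel width
`w` and the projected area is conserved, so the major axis becomes
`Dx = D0^2 / w` and the in-channel deformation index is `DI = D0 / w`. In
the chamber downstream the major axis relaxes to
`D0 (1 + rho (D0/w - 1))`, a linear interpolation between full recovery
(`rho = 0`) and full retention (`rho = 1`); the minor axis again conserves
area. This is deliberately the simplest model that reproduces the two
qualitative facts the analysis must recover — deformation inversely related
to channel width, and partial retained deformation downstream — without
asserting any cell mechanics (no stresses, no viscoelasticity, no fluid
simulation). Flow itself is abstracted to frame advance: the generator
renders one snapshot per region, as if flow were interrupted for imaging at
each location, and makes no claim about shear stress or transit time.

Defaults: baseline diameter 15 ± 1 µm (melanoma-like), retention fractions
`rho = 0.58` after the 10 µm channel and `0.26` after the 5 µm channel
(chosen so the default cells retain roughly +30% and +50% median
deformation, the regime of interest for a partially retaining cell line;
wider channels never deform 15 µm cells so their `rho` is irrelevant and set
to 0). Cells render at intensity 1000 over background 100 with Gaussian
read noise scaled by the square root of the signal (a standard camera
model).

`D0` pairing: when region snapshots can be linked (the generator keeps each
cell in its own flow lane), each cell's own baseline major axis is used as
`D0`; otherwise the cohort median baseline major axis is the fallback
(`d0_strategy="cohort"`). Both conventions are exposed because tracking is
not always available in practice; summaries report which was used via the
shape table.

## Deformation statistics

`% median deformation = 100 x median(region DI) / median(baseline DI)` and
`% increase` is that value minus 100; both are always reported so either
reading of "percent deformation" is available. Medians of even-length
samples are the mean of the two central order statistics (pinned so the
statistic is exactly testable). Groups under 20 cells trigger a warning
rather than an error: 20 is the minimum the headline statistic is defined
over, but smaller groups are still useful during exploration.

## Illumination model and correction

Observed images are modelled as `truth x flatfield + darkfield + noise`,
with the flatfield a smooth multiplicative field of mean 1 (the generator
injects a radial quadratic vignette with a configurable corner/centre
ratio) and the darkfield a small additive offset. Estimation from a frame
ensemble:

* **Darkfield** — smoothed per-pixel median across frames. With sparse
  content (objects cover a minority of each frame) the per-pixel median is
  the additive offset.
* **Flatfield** — each frame is foreground-thresholded with MCET and the
  per-pixel mean of foreground values accumulated across frames. This
  *conditional* mean is proportional to the multiplicative field regardless
  of how unevenly objects happen to cover the frame, which matters: the
  unconditional mean content is dominated by coverage fluctuations at any
  realistic number of frames. A quadratic surface is fitted to it (weighted
  by visit counts), clipped positive and normalized to mean 1. A second
  pass re-thresholds on vignette-corrected frames so dim objects in dark
  corners are not dropped from the foreground, which would otherwise bias
  corners upward.

A quadratic surface cannot represent higher-order illumination patterns;
for the smooth vignettes of wide-field optics it is adequate and makes
corner extrapolation stable. Fewer than 8 frames degrades the estimate
(warning); an all-zero channel returns the identity model. Correction is
`(observed - darkfield) / flatfield`, clamped at zero with the clamp count
recorded.

## Thresholding and segmentation

`mce_threshold` minimizes the cross-entropy objective
`-m1_below log(mu_below) - m1_above log(mu_above)` exhaustively over all
histogram cuts (`m1` the first moment, `mu` the class mean of each side).
8-bit images use their native 256 gray levels so the result is directly
comparable with a per-gray-level search; float images are histogrammed on
256 bins over their range. Ties take the lowest cut; constant images raise.

Nuclei are connected components above the DAPI MCE threshold with
components under `min_area_um2` (default 20 µm²) removed. Touching nuclei
can be split by a watershed seeded at distance-transform maxima with a
minimum seed separation (default 4 µm); curvature-based seeding was
considered but the distance transform is deterministic, standard, and
sufficient for convex nuclei. Cell bodies come from a watershed on the
inverted actin intensity restricted to the MCE foreground, seeded by the
nucleus labels, so every cell inherits its nucleus label, foreground
components without a nucleus are discarded, and a nucleus outside the
foreground keeps its own pixels as its cell (flagged). Cytoplasm is the
exact per-label set difference, so `area(cell) = area(nucleus) +
area(cytoplasm)` holds identically. Cells touching the image border are
flagged and dropped by default (partial cells bias area and axis
statistics).

Morphology uses the second-central-moment ellipse (major/minor axis of the
ellipse with matching moments), the standard deterministic definition of
"major axis" for an arbitrary region.

## Single-cell statistics

The parsing pipeline order is fixed: QC flags → IQR outlier removal →
robust-Z → PCA (97% variance) → 2-D embedding. Conventions, each pinned
because the statistic is only testable once a convention is chosen:

* Quantiles use linear interpolation between order statistics (the common
  scientific-computing default), so the fence of `{1..9, 100}` is exactly
  `[-3.5, 14.5]`.
* Outlier strata are condition x timepoint; a cell is removed when *any*
  feature leaves its fence (union rule).
* Robust Z is `(x - median) / (1.4826 MAD)`; the constant makes the scale
  consistent with a normal SD. Zero-MAD features are dropped from embedding
  input with a warning.
* PCA keeps the fewest leading components reaching 97% cumulative explained
  variance; component signs are fixed by making each component's
  largest-magnitude loading positive.
* The UMAP embedding is seeded and treated strictly as a visualization aid:
  no downstream statistic consumes embedded coordinates.
* Control-median centring (`value - control median`, per marker and
  timepoint) operates on unstandardized values, for plots and heatmaps.
* Mann-Whitney U uses midranks; the two-sided p is exact by full
  enumeration when `n_A + n_B <= 12` with no ties (enumeration is cheap and
  the oracle checkable there) and otherwise the normal approximation with
  tie and continuity corrections, which stays within 0.01 of the exact
  value by n = 10 vs 10.
* BH correction runs across timepoints within one feature by default
  (`bh_family="global"` pools everything), delegated to statsmodels'
  step-up implementation.
* Marker fold changes are means of per-cell mean intensities
  (treated/control), whole-cell compartment by default; median-based
  estimators are available through the comparison table, which reports
  median fold changes alongside.

## Dynamics

Calcium fold change is `max(in-region intensity) / mean(baseline
intensity)` — the maximum, not a baseline-subtracted ΔF/F, because the
summary of interest is a multiplicative influx factor. Because the max of a
noisy trace is upward biased by roughly one noise SD, recovered fold
changes sit slightly above the injected amplitude at high noise; this is a
property of the max convention, not an implementation error.

Permeability uses the two-compartment exchange model
`dI/dt = P (S/V) (I_vessel - I)`: an OLS slope over the initial fit window
(default 10 frames at 2-minute spacing) gives
`P = (V/S) slope / (I_vessel - I(0))` in cm/s for S/V in 1/cm. The
surface-to-volume ratio is user-supplied geometry (default 2 cm⁻¹, a
millimetre-scale tissue chamber). The estimator is accurate while
`P (S/V) t_window` stays well below 1 and biased low beyond it (the
exponential flattens); `fit_frames="auto"` truncates the window where the
tissue signal has risen 15% of the way to the vessel intensity, keeping
leaky-barrier fits in the linear regime. Negative slopes clamp to P = 0
with a flag.

## Tumorsphere growth

Sphere area grows linearly in the generator (`A(t) = A0 + r t`), spheres
render dark on bright brightfield background, and segmentation is MCET plus
hole filling with the minority intensity class taken as the blob. Growth
rate is the OLS slope of area vs day — areas look linear over a week and a
rate ratio needs no richer model — and requires at least 3 timepoints.

## DEG thresholds

`up` means p < 0.01 and log2FC > 0.6; `down` mirrors it; everything else is
`ns`. The fold-change equivalent of the 0.6 cutoff is 2^0.6 ≈ 1.5 at two
significant figures. The p comparison operator is configurable (`p_op`)
and classification uses raw p by default, with `use_adjusted` switching to
an adjusted-p column. Top-n selection sorts qualifying genes (p < cut)
ascending by p with ties broken by |log2FC| descending then gene id, so the
selection is deterministic.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis assumes:
ellipse cells with width-dependent elongation, non-overlapping two-
compartment cells under smooth illumination bias, lognormal cell-to-cell
intensity variability, piecewise-constant calcium gains, first-order dye
exchange, linear sphere growth. Passing tests therefore demonstrate that the
estimators recover known parameters under those assumptions, that the
conventions (medians, quantiles, fences, thresholds) are implemented
exactly, and that the statistical stack is calibrated (false-positive
fraction at or below nominal on null plates, near-complete detection of a
1.5-fold effect at 200 cells/group). They do not demonstrate robustness to
what the generator omits: point-spread blur, debris and overlapping cells,
heterogeneous intra-cell texture, focus drift, non-quadratic illumination,
photobleaching, or mechanical realism of deformation. Touching-object
robustness is tested separately with constructed touching-blob fixtures
rather than in the plate model, which keeps ground truth unambiguous.

## Problem sizes and numerical choices

Tests and the acceptance script run the study-scale conditions where they
are cheap (20 cells per region for deformation; 8-well plates with 25
cells/well, 200 cells/group for power; 500 null plates; 100 seeded runs for
growth and calcium) and a 24-well ensemble for flatfield recovery, half the
well count of a full plate experiment and ample for a six-parameter
surface. All generators draw from `numpy.random.default_rng` with explicit
integer seeds; identical seed and parameters give bit-identical output.
Degenerate inputs are defined behaviour, not crashes: blank images give
empty masks, empty compartments give missing means with QC flags, constant
features drop from embedding with warnings, and zero denominators raise or
flag as documented per function.
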