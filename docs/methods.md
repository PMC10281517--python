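# Methods

This note documents the models, parameter choices and numerical conventions
behind organoquant, and what the synthetic-data tests do and do not
demonstrate about real microscopy data.

## KTR kinetics model

The cytoplasm/nucleus ratio of a kinase translocation reporter is modelled
per cell as first-order relaxation toward an activity-dependent steady
state:

    dr/dt = (r_inf(a) − r) / τ,    r_inf(a) = r_min + (r_max − r_min)·a

with latent kinase activity a(t) ∈ [0, 1]. This is deliberately the simplest
model that reproduces the observed phenomenology — nuclear-enriched
fluorescence under kinase inhibition, cytoplasm-enriched under stimulation,
with a smooth transition over a two-hour movie sampled every 10 minutes. It
makes no claim about reporter biochemistry (import/export rates,
phosphosite kinetics) and is swappable: any function producing a per-frame
ratio trace can drive the renderer.

Because activity is piecewise constant between samples, the integrator
applies the exact per-interval exponential update
`r(t+Δ) = r_inf + (r − r_inf)·e^{−Δ/τ}`; agreement with the closed form is
at machine precision rather than a solver tolerance.

Defaults (free parameters; there are no established numeric baseline or
plateau C/N values for these reporters in organoids, so these are generator
conventions, not biological claims):

| parameter | default | meaning |
|---|---|---|
| r_min | 0.4 | C/N ratio, kinase fully inhibited (nuclear-enriched) |
| r_max | 2.5 | C/N ratio at saturation (cytoplasm-enriched) |
| τ | 15 min | relaxation time; visible translocation within 1–2 frames |
| noise_sd | 0.05 | multiplicative Gaussian intensity noise |

## Rendering and ground-truth masks

Cells are concentric disks (nucleus radius 5 µm inside a 10 µm cytoplasm
footprint) placed on a jittered grid with non-overlapping footprints. All
geometry is specified in micrometres and rasterised at 0.5 µm/px (typical of
a 25–40× confocal acquisition); pixel (r, c) has its centre at (r, c).
Per-compartment reporter intensity is uniform with I_c/I_n equal to the
requested ratio, so the mean-of-region estimator is unbiased and CLT error
bounds are analytic. Compartment edges are anti-aliased over a one-pixel
band; those pixels belong to *neither* compartment in the ground truth,
removing boundary ambiguity from recovery tests. An additive background
floor (default 0 for the reporter channel, so noise-free measured ratios are
exact) and multiplicative Gaussian noise are applied after composition.

## Segmentation and the ring cytoplasm

Nucleus segmentation is Gaussian smooth → threshold (Otsu or fixed) → fill
holes → minimum-area filter, with optional distance-transform watershed
splitting. Published organoid KTR analyses typically segment in
CellProfiler with unreported settings; since the verification surface here
is recovery on synthetic ground truth, a standard transparent pipeline with
every parameter exposed is preferable to replicating a specific tool's
internals.

The cytoplasmic compartment of cell k is the set of pixels reachable within
`ring_width` (default 5) successive one-pixel morphological dilations of
nucleus k, excluding all nucleus pixels. Dilation uses the 3×3 square
structuring element by default (step distance = Chebyshev distance;
`connectivity=1` gives the cross element / city-block distance) — the ring
area depends on this choice, which is why it is explicit. A pixel reachable
from several nuclei is assigned to the nucleus reached in the fewest steps;
ties go to the smaller label, or the pixel is dropped with
`exclude_contested=True`. Descriptions of the 5-pixel ring in the
literature do not specify 4- versus 8-connected dilation or the handling of
contested pixels; both options are exposed and the defaults are documented
rather than claimed.

**Rim guard.** The boundary of a segmented nucleus falls on the blurred
(anti-aliased) rim where nuclear and cytoplasmic signal mix; including those
pixels biases C/N ratios by several percent in a ratio-dependent way that
normalisation does not cancel. `rim_guard_px` (default 1) therefore measures
the nuclear mean on the segmentation eroded by one pixel and grows the ring
from the segmentation dilated by one pixel (the ring keeps its full width;
it just starts beyond the rim). With the guard, noise-free recovery of
ground-truth ratios is exact to machine precision. Setting `rim_guard_px=0`
restores the plain ring-from-segmentation behaviour.

## Ratio traces and statistics

Per-cell ratio = mean ring intensity / mean nuclear intensity; cells with
nuclear mean below 1% of the channel dynamic range are excluded
(division guard, configurable), as are cells with no ring pixels. Every
measurement in a movie cohort is normalised to the mean ratio over all
scored cells at the first time point (×100), pooling z planes; per-plane
normalisation is available by grouping keys. Per-organoid traces are
unweighted arithmetic means across cells per time point; the 95% band is
mean ± t(0.975, n−1)·sd/√n (a t interval because n is tens of cells); with
n = 1 the interval is reported missing, never zero. T0-versus-Tk comparisons
use one-way ANOVA on unweighted replicate-organoid means — replicate means
are the experimental unit, and organoids of different cell counts are not
weighted because the cohort mean, not the cell, is the replicated quantity.

Cohort means need no cell identity over time, so frames are analysed
independently by default. When per-cell traces are wanted, a greedy
nearest-neighbour centroid matcher with a displacement cap supplies
identities; it is deterministic (pairs matched in order of increasing
distance, ties by smaller label) and, like any coordinate-only matcher,
cannot distinguish two cells exactly exchanging positions from a static
scene — a documented limit, not a defect.

Mann–Whitney U uses exact enumeration of the null distribution of U
(dynamic-programming recurrence) whenever both groups have ≤ 20
observations and no ties — figure-style comparisons have small n, where the
exact branch matters — and otherwise the normal approximation with tie and
continuity corrections. Two-sided exact p doubles the smaller tail, capped
at 1. Welch's t and one-way ANOVA delegate to scipy with explicit
degenerate-input handling: identical pooled values give p = 1, zero
within-group variance with distinct means gives a p floored at machine tiny
rather than 0. No multiple-testing correction is applied by default (the
reported comparisons are per-figure, per-test); a Benjamini–Hochberg helper
exists for completeness.

## Morphometrics

Cell axes are measured from annotation line segments, not automatic
junction tracing: length = Euclidean endpoint distance × pixel size, and
length/width = lateral / width, with width measured through the nucleus
centre. Cells flagged as rounded/dividing (not integrated into the
epithelial sheet) are excluded and logged. Nucleus circularity is 4πA/P²;
the polygon branch uses shoelace area with the exact vertex-chain perimeter
and rejects self-intersecting outlines naming the crossing edge pair; the
mask branch uses the 4-direction Crofton perimeter estimator, because naive
pixel-edge counting overestimates perimeters and can push circularity above
1. Positivity thresholds are explicit (fixed, or Otsu over per-nucleus
means). The budding/spherical cut at solidity 0.92 was fixed after sweeping
the synthetic silhouette suite (disks vs 2–5-lobed shapes, 200 seeds, zero
misclassifications with a wide margin: spherical ≥ 0.99, lobed ≤ 0.87); on
real images it is a surrogate reported alongside, and overridden by, manual
phenotype labels.

## Epithelium generator geometry

Cells are trapezoids tiling a circular contour: basal edges are arcs on the
basal circle (so the closure identity Σ basal = 2πr holds exactly), lateral
extent is radial, and the apical edge is a centred shorter arc at radius
r_b − lateral, giving apical constriction when apical < basal. When the
contour radius is omitted it is derived from closure (r = n·basal/2π);
an explicitly supplied incompatible radius is rejected with the feasible
n_cells range. Per-cell lengths are Normal draws about the spec means;
angular widths are rescaled to close the ring exactly and the *realised*
lengths are what ground truth records. Annotation segments are straight
lines of exactly the ground-truth length (radial midline; tangents at edge
midpoints), mirroring how a human draws measurement lines, so the
annotation→measurement round trip is exact by construction.

## What the synthetic tests do and do not show

Passing recovery tests demonstrates that the measurement chain — plane
selection, segmentation, ring construction, intensity statistics,
normalisation, aggregation, significance testing — is internally correct
against known truth. The generator deliberately omits point-spread-function
blur, photobleaching, depth attenuation, cell movement and division,
segmentation-relevant texture inside nuclei, and 3-D light-sheet geometry;
performance on real images therefore depends on segmentation quality in
ways these tests cannot certify. Problem sizes in the tests (20-cell
movies, 13 frames, 100-cell epithelia, 200-silhouette sweeps, 10⁴ null
simulations) are the package's verification conventions, chosen to make
every property checkable in seconds to minutes.

## Numerical conventions

Coordinates are 0-based (row, column) with the pixel-centre convention;
areas are pixel counts × pixel_size². Images are written as 16-bit
(T, Z, C, Y, X) TIFF; tables as UTF-8 CSV with a JSON sidecar recording
package version, config hash and seed. Positive-count rounding is
half-away-from-zero so generated scenes have a countable target. All
generators are deterministic given (spec, seed); every source of randomness
in the CLI and acceptance script derives from the recorded seed.
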