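# Methods

`nucleotrack` quantifies the stepwise condensation of the bacterial
nucleoid ("DNA supercompaction") that follows severe DNA damage — e.g.
fluoroquinolone exposure in *E. coli* — from multi-channel time-lapse
fluorescence microscopy.  Because raw microscopy archives are large and
detector settings are instrument-specific, the package ships a synthetic
scene generator with exact ground truth; every quantitative claim the test
suite makes is validated against that truth or against a closed-form
oracle.

## The kinetic model of supercompaction

Each cell progresses irreversibly through

    multifocal -> quarter-position -> {midcell | periseptal}

after a deterministic lag `lag_min` (default 8 min, matching the observed
onset window of roughly 8–20 min post-exposure).  Both steps are
first-order with rates `k1`, `k2` (defaults 0.25 and 0.35 /min); the
terminal branch is periseptal with probability `p_periseptal` (default
0.15) when a forming septum blocks full convergence at midcell.  Dose maps
to rate through a Hill function
`k_eff = k_max * d^h / (d^h + ec50^h)`, which is monotone in dose, so the
model reproduces dose-ordered progression by construction.

The closed-form endpoint occupancy (fraction of cells at midcell or
periseptal by time `t`, with `tau = t - lag`):

    P_end(t) = 1 - (k2 e^{-k1 tau} - k1 e^{-k2 tau}) / (k2 - k1)

with the `k1 = k2 = k` limit `1 - e^{-k tau}(1 + k tau)`.  This formula is
the oracle for the stochastic simulator (binomial-CI agreement at 500–1000
cells) and for the crossing-time metric below.

Per-frame state updates use exact exponential step probabilities
`1 - exp(-k dt)`, with partial-step handling at the lag boundary so the
lag is honoured regardless of frame alignment.  The update routine takes
the elapsed time at the start of the step for this reason.

## The synthetic scene

Static spherocylindrical cells (length 2.5–4 um, width 0.8–1.0 um,
uniform random orientation) are placed without overlap (2-px exclusion
margin; a bounded-retry placement raises a capacity error when the
requested density cannot be met).  Cells are static because the drug
regime being emulated arrests division, and static cells make tracking
ground truth exact.

Channels:

* **TL** — inverted interior with a darker rim on a bright field; enough
  structure for threshold segmentation, deliberately not an optics model.
* **DNA** — an axial Gaussian-mixture template per state, all templates
  normalized to the same integrated intensity (compaction redistributes
  signal; the renderer conserves it to <1%):
  * multifocal: four blobs at ±0.12 L and ±0.36 L, outer blobs brighter
    (weights 0.3/0.2/0.2/0.3) — two nucleoids of two lobes each;
  * quarter: two equal blobs at ±0.25 L;
  * midcell: one blob with sigma = 0.187 L, chosen so the 80%-of-maximum
    width of the profile is ~25% of cell length;
  * periseptal: two tight blobs (sigma 1.2 px) flanking a 2-px septum gap,
    plus a faint bridge component (weight 0.3) across the gap.  The bridge
    keeps the two lobes inside a single thresholded region while the two
    intensity peaks stay separate — exactly the (2 maxima, 1 focus)
    signature that distinguishes periseptal from quarter compaction
    downstream.  Blob geometry was fixed once, from the detector defaults,
    before any end-to-end evaluation.
* **Optional focus channels** — punctate pole/nucleoid foci for a
  RecN-like and a RecA-like reporter, with a configurable planted
  colocalization rate.

Rendering convolves with a Gaussian PSF (sigma 0.1 um), adds a planar
background with a mild gradient, then Poisson shot noise at
`photon_scale` photons per intensity unit and Gaussian read noise.  SNR is
defined as the dimmest state-template blob peak (the multifocal inner
lobe) over the background noise SD (shot and read noise in quadrature);
`read_noise_for_snr` solves for the read noise that hits a target SNR.

What the generator does **not** emulate: cell growth and motility, focus
drift, photobleaching, optical aberrations beyond a Gaussian PSF, cell
debris and touching cells, or intensity heterogeneity within a state.
Passing tests therefore demonstrate correctness of the measurement
pipeline under controlled conditions, not robustness to every real-world
artifact.

## Preprocessing

Best-focus slice selection maximizes normalized intensity variance
(var/mean^2), with ties broken to the lowest z index.  Flat-field division
uses a mean-normalized reference.  Fluorescence background is removed by a
sliding-paraboloid opening: grayscale erosion+dilation by a paraboloid
surface of apex curvature radius `radius_um` (default 1 um).  Because the
paraboloid is an additive sum of per-axis parabolas, the 2-D operation
factors exactly into two 1-D passes, which keeps it fast.  Output is
clamped at zero.  The TL channel instead gets a signed median-filter
subtraction (2 um disk) or a 1–2 px Gaussian blur (default 1.5 px).

## Segmentation and medial-axis geometry

Foreground is Otsu-thresholded (cells dark by default), connected
components are labeled, and each component's medial axis is the
skeleton pruned to its longest path (double BFS), smoothed, and extended
along its end tangents to the pole caps — skeletons stop about one
half-width short of each pole, so the extension recovers the true length.
Near-round components whose skeleton collapses to a point fall back to
the inertia-tensor major axis.

Descriptors: length = axis arc length; width = twice the mean distance
from the axis core to the smoothed sub-pixel (0.5-level) outline — this
is orientation-stable where the integer distance transform is biased by
rasterization; sinuosity = arc length / end-to-end distance; curvature
and angularity from turning angles of the smoothed, 2-px-resampled axis.
The default geometric acceptance window (area 1–15 um^2, length 1.5–15 um,
width 0.5–2 um, sinuosity ≤ 1.3, curvature ≤ 1 /um, angularity ≤ 0.5 rad)
is config-overridable, and rejection reasons are reported per cell.

Division sites are interior local minima of the axial width profile below
0.4x the median width, at least 15% of the length away from either pole
(guarding against cap artifacts); the cell is split by nearest-axis-vertex
assignment, which partitions the parent mask exactly.

Tracking links cells frame-to-frame by greedy descending mask IoU with a
floor (0.3); links below the floor terminate tracks rather than risk
identity swaps, there is no gap closing, and runs shorter than 10
consecutive frames are discarded.

## Two-tier spot model and phenotype classification

Point maxima are strict 8-neighborhood local maxima of the 1-px-smoothed
in-cell image whose height above the in-cell minimum exceeds 20% of the
in-cell dynamic range (a rule invariant to constant offsets), thinned to a
minimum 3-px separation keeping the higher peak.  Region foci are
connected components above the in-cell mean + 2 SD (≥ 4 px).  The two
tiers are independent on purpose: a merged septal region with two internal
peaks is the periseptal signature.

Classification per cell per frame from (n_maxima, n_foci):
multifocal if n_maxima > 2; midcell if n_maxima == 1 (focus count
immaterial); quarter if n_maxima == 2 and n_foci > 1; periseptal if
n_maxima == 2 and n_foci == 1; otherwise excluded.  The clauses partition
all count pairs; (2, 0) and (0, anything) fall to excluded.  Fractions
are normalized to the total cell count per replicate — excluded cells
stay in the denominator (a classified-only denominator is available by
option).

The progression-rate metric is the first time the midcell+periseptal
fraction crosses 10%, linearly interpolated between the bracketing
samples; a series already above threshold at its first sample returns
that time flagged left-censored.  Linear interpolation is the package's
choice where the convention was open.

## Profiles, width statistic, kymographs

Axial profiles project each in-cell pixel to its nearest medial-axis
vertex and average intensity per axial bin (50 bins by default; empty
bins interpolated).  The symmetrized profile averages the profile with
its mirror.  The DNA-distribution statistic is the distance between the
*outer* bounds of the profile at 80% of its maximum, each bound refined
by linear interpolation; an interior dip below the threshold does not
terminate the span (two quarter-position peaks yield one wide span, by
design).  Kymographs are row-normalized profiles over time; population
kymographs first normalize each cell's profile to unit sum so long and
short cells contribute equally, averaging in normalized-length
coordinates.  Note that the central-axis mass transiently *dips* during
the quarter-position wave (mass sits at ±L/4) before rising sharply at
the midcell endpoint; epoch comparisons should bracket the transition.

## Colocalization and statistics

A query focus colocalizes with reference regions when its centroid pixel
falls inside any region dilated by an integer margin (8-connected;
margin 0 = strict containment).  Margin 0 is the DNA-vs-RecN convention,
margin 1 the RecA-vs-RecN convention.  The rule is monotone in margin.

The midcell-proximity contrast is, per replicate, the mean relative
midcell distance of colocalizing minus non-colocalizing foci; replicate
deltas are tested against zero with a one-sample t (n = replicates), with
a 95% t-interval on the replicate-mean scale.  Degenerate inputs (all
deltas identical) take an explicit t=0/p=1 or p=0 path.  Group
comparisons use Welch's t with Satterthwaite degrees of freedom (formulas
implemented directly; validated against an independent implementation to
1e-10) and Holm–Šidák step-down adjustment (via statsmodels'
`multipletests`, validated against the explicit step-down formula).

## Problem sizes and numerical choices

End-to-end validation runs three replicates of 300 cells on a
1024x1024 px canvas over eight 2-min frames, in a noise-free and an
SNR=5 regime; these sizes give per-frame phenotype counts in the
thousands while keeping a full run in minutes on one core.  Crossing-time
validation uses 1000-cell state-level simulations (no rendering), where
the closed form is the oracle.  Stochastic tests fix their seeds and use
binomial or Monte-Carlo error bands (2.6–3 SD) rather than exact
equality.  Ties in the focus-score and maxima searches break
deterministically (lowest index / higher peak).

## Known limitations

* The medial-axis formulation is a standard skeleton-based definition,
  not a reimplementation of any specific proprietary tool; absolute
  descriptor values (curvature, angularity) depend on the smoothing
  choices documented above.
* Sub-pixel spot localization is not attempted; focus centroids are
  pixel-level (point maxima) or intensity-weighted (regions).
* The classifier is exactly as sharp as its two detectors; at low SNR the
  dominant error mode is a periseptal cell read as midcell when its two
  peaks merge under smoothing.
* Axial focus position uses arc-length along the medial axis (not
  Euclidean distance to midcell); for near-straight cells the difference
  is negligible, and the choice is recorded here as an assumption.
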