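# Methods

## Contour model and the EFC dysmorphia statistic

A nucleus outline is a simple closed polygon in image coordinates
(x = column, y = row, origin top-left, pixel centers at integers).
Outlines are traced from binary masks by marching squares at the 0.5
iso-level of the lightly smoothed (Gaussian, sigma 1 px) zero-padded
mask. The smoothing removes the pixel staircase, which would otherwise
inflate perimeter by ~10% and leak spurious power into high harmonics;
the cost is slight rounding of true corners (a 10x10 square loses ~4%
of its polygon area). Contours are oriented counterclockwise.

The decomposition is the classic elliptical Fourier analysis under
cumulative chord-length parameterization: for harmonic k the
coefficient quadruple (a_k, b_k, c_k, d_k) is computed by closed-form
sums over polygon segments, and the DC terms (A0, C0) are the traversal
means. Before decomposition a contour is resampled to 256 points
equally spaced in chord length (512 in the high-accuracy tests). The
harmonic's *size* is the largest singular value of
[[a_k, b_k], [c_k, d_k]], i.e. the semi-major axis of the harmonic
ellipse; the total amplitude sqrt(a^2+b^2+c^2+d^2) is available as a
labelled config alternative. The dysmorphia statistic is

    EFC = size_1 / sum(size_2..size_15)

with K = 15 harmonics. Irregularity adds power to harmonics 2..15, so
lower EFC means greater dysmorphia. A nucleus is dysmorphic when its
EFC is less than or equal to the calibrated threshold (ties count as
dysmorphic). The threshold is the arithmetic mean EFC of a pool of
borderline contours; calibration is global across an analysis by
default, with per-directory pools supported.

Numerical choices:

- Denominator floor 1e-12 x size_1 keeps perfect ellipses finite; the
  resulting very large ratios are always on the non-dysmorphic side, so
  classification is unaffected.
- No contour smoothing beyond the mask-level sigma-1 trace: smoothing
  deflates harmonics 2..15 and biases EFC upward.
- No size or rotation normalization of coefficients: the ratio of
  singular values is scale- and rotation-invariant by construction.
- Before resampling, the traversal is canonicalized (counterclockwise,
  start at the vertex farthest from the vertex mean). This makes the
  EFC ratio exactly invariant — not merely approximately — to cyclic
  relabeling of the start point and to traversal-direction reversal,
  because both produce bit-identical resampled polygons.
- Zero-length segments (repeated points) are dropped before
  decomposition; fewer than 16 surviving points is an error.
- Chord-length resampling is only approximately idempotent: equal steps
  in polygonal arc length produce chords of curvature-dependent length,
  so a second resample lands off-vertex by O(step^2) (~5e-3 px at 128
  points). Exact idempotence is impossible for this parameterization.
- K = 15 truncation reproduces lobed contours to <= 0.5 px (512
  points) for lobe orders up to 6 at lobe amplitude 0.2 — the amplitude
  used for dysmorphic-grade synthetic nuclei. Stronger lobing at high
  order (amplitude 0.3, order 6) carries real power beyond harmonic 15
  and reconstructs to ~1 px; this is a property of the statistic, not
  an implementation error. Reconstruction error is non-increasing in
  the number of harmonics in the RMS (L2) sense, by orthogonality; the
  maximum deviation can wiggle by a few hundredths of a pixel.

## Synthetic data generator

The generator emulates three-channel fluorescence fields (DNA stain,
actin, DNA-damage foci) with exact per-object ground truth. Its
purpose is validation: every downstream call (segmentation, EFC,
phenotype flags, focus counts, loop summaries) can be compared against
planted truth.

Shape model: a base ellipse with semi-axes (a, b) modulated radially by
1 + eps*cos(k*theta) plus optional smoothed Gaussian jitter. Because
the modulation is a positive single-valued radial factor, contours are
star-shaped and therefore simple; eps < 0.5 guarantees positivity.
Normal nuclei use eps <= 0.03, dysmorphic nuclei eps = 0.25 (scenes)
or 0.2..0.35 (contour populations); lobe order is drawn from 3..6.
This gives analytic control of harmonic content — EFC is monotone
decreasing in eps at fixed order — which real imaging data cannot
provide.

Scene layout: cell centers are placed by rejection sampling with a
hard-core distance that forbids overlap by construction (bounded
retries; exceeding them raises an error naming the achievable count).
Default primary-nucleus radius 18 px, image 512x512 and up, background
10, nuclear foreground 200 intensity units. Micronucleated cells carry
a satellite body at 1.6 radii from the primary with radius 0.22..0.28
of the primary's (area fraction 0.05..0.08, comfortably below the 1/9
micronucleus cutoff). Multinucleated cells carry two nuclei at 0.7
scale placed 1.7 radii apart, size-matched so each exceeds half the
larger one's area. Foci are isotropic Gaussian spots of width
psf_sigma (default 1.5 px) and amplitude 150 over background, planted
uniformly in the eroded nucleus interior with pairwise separation of at
least 6 psf_sigma; counts are Poisson with the configured rate.
Imaging applies PSF blur (except to the foci channel, whose spots are
already rendered at PSF width), Poisson shot noise, and additive
Gaussian read noise (sd 2). All randomness flows from one explicit
seed; identical configs render bit-identical scenes.

What the generator does not emulate: uneven illumination, chromatic
shift between channels, out-of-focus light, intensity texture inside
nuclei, touching/overlapping cells, imaging depth (3D), or the full
morphological variety of real dysmorphic nuclei (blebs, bridges,
folds). Passing recovery tests therefore demonstrates correctness of
the measurement pipeline on well-posed inputs, not robustness to every
real-microscopy artifact.

## Segmentation and cell grouping

Whole-field mode: Gaussian pre-smooth (sigma 1 px, chosen to suppress
JPEG blocking since crops are often stored as JPEG), global Otsu
threshold (numeric override available), hole filling, removal of
objects under min_area_px (default 30 px), optional distance-transform
watershed whose marker spacing is derived from the median candidate
object radius. A foreground/background contrast guard (mean difference
at least 4 background sds) returns an empty mask instead of
thresholding pure noise; zero-variance images likewise yield an empty
mask with a warning. Border-touching objects are flagged and excluded
from shape scoring by default, since partial contours bias EFC.

Single-nucleus mode mirrors analyses where each image file holds one
manually cropped nucleus: the largest thresholded component is kept,
smaller specks are counted and discarded, unusable crops are skipped
and reported.

Cells are formed from nuclei either by shared actin region (each
nucleus is assigned to the segmented actin component under its
centroid) or, absent an actin channel, by single-linkage merging of
nucleus centroids within link_radius_px (default 40 px — about two
nucleus diameters at typical 20x magnification).

## Phenotype rules

Scoring is per cell over non-exclusive categories, all percentages
sharing one cell denominator, reported per replicate and pooled:

- micronucleus: area <= 1/9 of the primary (largest) nucleus — the
  conventional "diameter under one third" criterion — and centroid
  within micro_max_dist_px (default 60 px) of the primary. These
  cutoffs are conventions of this package (visual scoring is the field
  norm) and are echoed into output metadata.
- multinucleated: at least two non-micronucleus nuclei each with area
  >= 0.5 of the primary, so micronuclei can never trigger the flag.
- dysmorphic: any non-micro nucleus at or below the EFC threshold.
  Micronuclei are not shape-scored; they are too small for stable
  15-harmonic fits.

## Focus detection and positivity

Per nucleus, intensities are centred on the in-mask median and scaled
by a one-sided MAD: the spread is estimated from pixels below the
median only, because foci push intensities exclusively upward and a
two-sided MAD is inflated when foci cover an appreciable fraction of
the nucleus. Detection is multiscale Laplacian-of-Gaussian (sigma
1..3 px, 5 steps) on the masked, normalized image; candidate blobs must
have peak z >= 5 (min_prominence_rel), sit at least 2 px inside the
mask (a focus centered outside leaves a truncated half-spot peaking at
the boundary), and blobs closer than twice their scale are merged,
keeping the brightest. Pixels outside the mask are zeroed first, so
content elsewhere in the field can never change a count. Per-nucleus
normalization means staining-intensity differences between conditions
do not masquerade as focus-count differences. A nucleus is positive
with >= 5 foci; the threshold is a parameter so the percentage can be
re-evaluated without re-detection.

## Hi-C loop summaries

The package consumes upstream loop calls (6+-column BEDPE, 0-based
half-open) and read-pair tallies; it does not align reads or call
loops. Loop span is the distance between anchor midpoints (outer span
available as an alternative; published "loop size" definitions vary and
are rarely stated). Loops match across conditions when they share the
chromosome pair and both anchor midpoints agree within anchor_tol_bp
(default 0; set to the caller's bin size in practice). Matching is
greedy nearest-midpoint, one-to-one, ties broken by genomic order — a
deterministic choice; unmatched loops are "unique" to their condition.
Read pairs are cis-short (< 20 kb), cis-long, or trans; the three
percentages always sum to 100. Condition comparison reports the
unique-loop counts and fold change, span statistics, and a two-sided
Mann-Whitney U on the unique-span samples — exact enumeration of all
C(n+m, n) splits when n+m <= 20, normal approximation with tie
correction otherwise. Empty sets propagate as missing values, never
as zeros.

## Statistical tests

compare_groups dispatches two-sided tests throughout: unpaired t,
Mann-Whitney U, Wilcoxon signed-rank (zero differences dropped,
Wilcoxon's convention; all-zero differences are reported as undefined
rather than silently p = 1), and chi-squared on an r x c table without
continuity correction by default. Significance display uses
alpha = 0.05, and no multiple-testing correction is applied — callers
running many comparisons must correct externally.

## Problem sizes used in validation

Contour-level checks use 512-point contours; invariance is checked over
100 randomized lobed contours under five transforms each.
Classification recovery uses 200 normal + 200 dysmorphic contours with
a 20-contour borderline pool bisected to the EFC of an amplitude-0.12
reference. Scene-level phenotype recovery uses four 50-cell fields
(200 cells) at planted fractions 0.2/0.1/0.3. Focus recovery uses 64
nuclei at rate 6; the Poisson-tail check uses 200 nuclei in
radius-24 px scenes (at the default 18 px radius the minimum-separation
constraint truncates high Poisson draws and biases the tail; see the
generator section). Toy loop files use a 10 shared / 5 + 3 unique
partition over three chromosomes.

## Known limitations

- Absolute EFC values depend on the resampling density, harmonic count
  and size definition; different shape-analysis software normalizes
  differently, so only the direction of the statistic, the ordering of
  shapes, and the threshold semantics are transferable across tools.
- The watershed splitter handles modest overlap between two nuclei; it
  is not a general declumping solution for dense fields.
- Focus counting is 2D and count-based; it does not estimate focus
  intensity or handle overlapping foci closer than ~2 PSF widths.
- Loop matching is midpoint-based; callers that report re-binned or
  merged anchors require a nonzero tolerance chosen by the user, and
  results should be reported together with that tolerance.
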