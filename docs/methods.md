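# Methods

## Problem setting and model

Under transillumination, optical density is roughly proportional to tissue
thickness, so a leaf image has three well separated intensity classes:
bright background, mid-gray blade, and darker regions where one lobe lies
over the blade (double thickness). Sinuses enclosed by touching or
overlapping lobes remain background-bright. The package models the leaf
margin as a single closed polygonal ring that may self-intersect (at the
pair of cross points flanking each overlapping lobe) or self-contact (at
the touch point of a closed sinus), and recovers that ring by composing the
outlines of all regions visible in a two-level segmentation.

## Segmentation

* `max_entropy_threshold` is the Kapur–Sahoo–Wong criterion on the 256-bin
  histogram: it returns the integer t ∈ [0, 254] maximizing the sum of
  Shannon entropies of the dark (≤ t) and bright (> t) classes. Ties break
  toward the smallest t for determinism. Constant images raise.
* `default_threshold` is iterative intermeans
  (t ← ⌊(mean(≤t) + mean(>t))/2⌋) started from the midpoint of the
  *occupied* intensity range. The starting point matters on trimodal leaf
  histograms: started from bin 127 the iteration can converge into the
  overlap/blade gap, which is not the whole-leaf split this threshold is
  for. The exact legacy "default" variant differs between imaging tools;
  this implementation is documented as an intermeans approximation and is
  cross-checked in the tests against an independent fixed-point oracle.
* Mask polarity: the inverted-T1 mask selects intensity > t1 (overlaps are
  its only background); the T2 mask selects intensity ≤ t2 (the leaf).
  Their XOR is the composite: blade dark; OL outlines, enclosed sinuses and
  background bright.
* `auto_thresholds` adds two robustness layers used by the pipeline and the
  CLI (the raw operations above keep their contracts):
  * *Gap snapping.* Automatic criteria often land in a class tail (the
    entropy criterion gains from including a sliver of the blade tail in the
    dark class). When a run of ≥ 4 empty histogram bins lies within 32
    levels of the returned threshold, the threshold is re-centered to the
    run's midpoint — classification-equivalent for separated classes, but
    maximally robust to noise. Histograms without such gaps (real scanner
    images with merged classes) are untouched.
  * *No-overlap detection.* Leaves whose lobes only touch have a bimodal
    histogram; both thresholds then find the same leaf/background split and
    the composite would collapse. Such leaves need only the single default
    threshold, so when the dark class of T1 covers more than half of the T2
    leaf, T1 is set to 0 and the composite reduces to the inverted T2 mask.
* `binary_close` (disk element, default radius 2 px, applied to the
  inverted-T1 mask) removes the thin dark traces thick venation leaves in
  the overlap class; `despeckle` (opening, default radius 1 px, applied to
  the composite) removes noise specks and 1-px bridges across the thin
  blade strips that separate bright regions. Both radii are configurable;
  radius 0 disables either step.
* The ±5% exploration panel rebuilds the composite for every
  (f1, f2) ∈ {0.95, 1.00, 1.05}², with thresholds rounded half-up and
  clamped to [0, 254]; the center entry is bit-identical to the unperturbed
  composite.

## Tracing and classification

Interior regions of the composite (bright 8-connected, dark 4-connected;
border-touching regions excluded; area ≥ `min_area`, default 16 px²) are
traced with Moore-neighbor boundary following and Jacob's stopping
criterion, starting from the topmost-then-leftmost region pixel, giving a
deterministic ordered ring of boundary-pixel centers (0-based x = column,
y = row, y down). Pixel centers rather than crack boundaries are a
convention choice; it shifts enclosed areas by a half-pixel band. The
largest ring is the blade; other regions are OL outlines when ≥ 50% of
their pixels are dark-class in the source image, else sinuses (the 50% rule
is this package's own automatic stand-in for visual identification).

## Junctions

For each contour pair, candidate junctions are vertex pairs at locally
minimal distance ≤ `d_adj` (default 2.0 px — adjacent outlines in the
composite sit 1–2 px apart), selected greedily by ascending distance with a
suppression window of `min_separation` = 10 vertices along either contour
so short stretches of near-contact yield one junction. A junction is a
cross point when either contour is an OL outline, a touch point otherwise;
a manual junction list can be supplied instead (JSON override). The
junction graph must connect all contours, else the error names the
unreachable ones.

## Concatenation

At a junction with nearest vertices a_c (on A) and b_c (on B), the chords
p = a1–b2 and q = a2–b1 (indices c−1 and c+1, modular) are tested for
intersection through their slopes and midpoint-form intercepts; the carrier
lines meet at Z, and the segments intersect iff Z lies in the common range
of the two segments' x- and y-intervals. The common range is implemented
as the *overlap* of the two segments' coordinate ranges, which makes the
Z-in-range test exactly equivalent to segment intersection for
non-parallel, non-vertical chords — the joint min/max hull of all four
endpoints would declare phantom intersections for skewed chord pairs.
Numerical guards: |Δx| < 1e-9 ⇒ the slope algebra is undefined and an exact
cross-product orientation predicate substitutes; |slope difference| < 1e-9
⇒ parallel ⇒ no intersection (collinear overlaps included).

Cross junctions require the chords to intersect, touch junctions require
them not to; on failure contour B — always the absorbed, smaller-|area|
contour, for determinism — is reversed (same starting vertex) and the test
repeated; failure in both orientations raises. The splice emits
[a_c, b_c, …tour of B…, b_c, a_c, …tour of A…]: n_A + n_B + 2 vertices with
both junction vertices duplicated. Junctions are processed in ascending
(x, y) of their location; after each merge remaining junction vertices are
re-located on the merged ring with a fresh nearest-vertex search (simpler
and robust to the duplicated vertices, rather than index translation);
junctions whose contours are already merged are skipped. Each effective
merge reduces the live count by exactly one.

The self-intersection signature is verified topologically: the ring is
clipped to a 5-px disc window around a junction, each maximal arc through
the window is reduced to its entry/exit angles on the window circle, and
two arcs cross iff their endpoints interleave — which resolves the doubled
splice chord (traversed once in each direction) without perturbation. A
correctly woven cross point scores 1 (two per overlapping lobe's pair of
cross points, the "slalom"), a touch point 0.

Silhouette checks fill the final ring with the **nonzero winding rule**,
implemented as a signed scanline algorithm: overlap regions are wound twice
and filled; sinus loops are wound oppositely and become holes, so the fill
matches the T2 leaf mask. (Even-odd filling — what common path-hit-testing
APIs effectively do on such rings — would drop the overlap regions.)

## Elliptic Fourier analysis

Kuhl–Giardina coefficients under cumulative chord-length parameterization,
computed with the exact piecewise-linear formulas (not an FFT), plus the
offset terms A0, C0. Consecutive duplicate vertices (the splice duplicates
junction vertices) are collapsed first, since zero-length chords are
undefined. Self-intersecting rings are processed identically — the
parameterization follows the vertex chain, which is the point of feeding
the concatenated contour to EFA. The inverse evaluates the truncated series
at uniform (or caller-supplied) parameter values; stepwise reconstruction
returns one ring per requested harmonic count. No size/rotation/phase
normalization is applied by default; the standard first-harmonic-ellipse
normalization is available explicitly and flagged in the output.

One property worth knowing: under chord-length parameterization only a
*circle* is exactly one harmonic. An eccentric ellipse traversed at
constant speed has x(t), y(t) that are not pure sinusoids; at 2:1 aspect
about 99.4% of the energy is in harmonic 1 and the third harmonic is ~7% of
the first in magnitude (even harmonics vanish by symmetry). The
single-harmonic idealization is therefore asserted only on
low-eccentricity fixtures (≤ 1.1:1, > 99.9% energy), and the 2:1 spectrum
is pinned against an independent numerical Fourier integral.

## Synthetic data

The generator renders: a polar blade r(φ) = r₀(1 + a·cos(kφ)) (defaults
r₀ = 120 px, a = 0.12, canvas 400×400, center at the integer pixel grid);
gray levels (230, 140, 60) for background/blade/overlap; additive Gaussian
noise σ = 3 clipped to [0, 255]; optional 1-px dark venation polylines to
exercise the closing step. Overlapping-lobe clusters are a disc-shaped
overlap region near a lobe apex plus a disc sinus on its inward side;
touching-lobe clusters are a disc sinus just inside the apex. Disc radii
and offsets are snapped to the pixel grid so the separating blade strips
rasterize to exactly the widths that put contour-junction distances at
2.0 px without 8-connected leaks between bright regions — which is why
clusters are only supported on axis-aligned lobe apexes (other placements
raise the infeasibility error). Ground truth (region label image, classes,
junction kinds/locations, expected contour count) follows from the
constructive geometry. The `fig1d` preset (four lobes, overlaps east/west,
touches north/south) reproduces the seven-contour worked configuration.

What the generator does *not* emulate: illumination gradients, blur and
partial-volume edges, petioles, real venation texture, damaged margins, and
overlap regions of irregular (non-disc) shape. Passing tests therefore
demonstrate the correctness of the algorithmic chain under clean,
well-separated intensity classes, not segmentation robustness on real
scanner images — for those, the threshold panel and the manual junction
override are the intended escape hatches.

## Problem sizes and determinism

Default study conditions: 400×400 px canvas (~160k pixels), rings of
~1100 vertices, 100-harmonic EFA round trips, 10⁴ random segment pairs for
the geometry oracle. Every random source is seeded (generator seed, oracle
RNG); two runs on identical inputs produce byte-identical contours,
coefficient files and reports.

## Known limitations

* Junctions where three or more contours meet at one point are not
  resolved.
* One nesting level: regions inside OL outlines are not expected.
* The crossing-number window assumes only the junction's two strands pass
  within 5 px; the presets guarantee this, arbitrary inputs may not.
* JPEG input is accepted with a warning, but compression artifacts blur the
  intensity classes the thresholds rely on; lossless formats are expected.
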