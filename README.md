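# leafknot

Closed-contour capture of leaves with **touching lobes (TL)** and
**overlapping lobes (OL)**.

Leaf shape is a standard taxonomic character, usually captured by automatic
contouring ("magic wand") of a thresholded leaf image. That breaks down for
species such as grapevine, fig or maple whose lobes grow until they touch or
fold over the blade: parts of the margin are then hidden or enclose closed
sinuses, and the outline can no longer be traced as one simple curve.
`leafknot` recovers the full margin as a single closed — and where lobes
overlap, *self-intersecting* — contour, from a transilluminated gray-level
image in which overlaps read as darker (double-thickness) regions.

The pipeline:

1. **Two-level segmentation.** A maximum-entropy (Kapur) threshold T1
   isolates the dark overlap regions; an iterative-intermeans ("default"
   bimodal) threshold T2 separates the whole leaf from the bright
   background. The pixelwise XOR of the *inverted* T1 mask with the T2 mask
   is a composite in which the blade is one dark region while OL outlines,
   enclosed sinuses and the background are separate bright regions. A 3×3
   panel of composites from ±5%-perturbed thresholds supports manual tuning.
2. **Contour tracing.** Every interior region of the composite is traced
   (Moore-neighbor boundary following) and classified as blade, OL outline
   or sinus.
3. **Junction localization.** Cross points (overlap) and touch points
   (contact) are found as locally minimal vertex-pair distances between
   contours.
4. **Concatenation.** At each junction, the chords p = a1–b2 and q = a2–b1
   around the junction-nearest vertices a_c, b_c are tested for intersection
   via their slopes, intercepts and the carrier-line intersection Z inside
   the segments' common coordinate range. A cross junction requires p∩q ≠ ∅,
   a touch junction requires p∩q = ∅; otherwise one contour is reversed.
   The rings are then spliced (`a_c → b_c → tour of B → b_c → a_c → tour of
   A`), reducing the contour count by one per merge until a single closed
   contour remains — weaving a "slalom" through each pair of cross points.
5. **Elliptic Fourier analysis.** The final ring is expanded in
   Kuhl–Giardina harmonics (a_n, b_n, c_n, d_n) under chord-length
   parameterization; self-intersections pass through unchanged. Stepwise
   inverse synthesis visualizes how lobes and overlaps accumulate with
   harmonic order.

A seeded synthetic-leaf generator (`leafknot.synth`) renders
transilluminated-style images with analytic ground truth (region classes,
junction kinds and locations, expected contour counts), so the whole chain
is testable without image downloads.

## Worked example

```bash
leafknot synth --preset fig1d --seed 1 --out leaf.png --truth truth.json
leafknot run leaf.png --out results/
```

prints

```
fig1d leaf (seed 1) -> leaf.png
T1=99 T2=184; 7 contours, 6 merges, final ring 1108 vertices
outputs: results/leaf.xy, results/coeffs.csv, results/report.json
```

The `fig1d` preset is a four-lobed leaf with two overlapping and two
touching lobes. T1 = 99 sits between the overlap (60) and blade (140) gray
levels, T2 = 184 between blade and background (230). The composite yields
**7 contours** — one blade, two OL outlines, two OL-closed sinuses, two
TL-closed sinuses — joined by 4 cross points and 2 touch points in **6
merges** (one fewer live contour per splice) into a single closed ring of
1108 vertices that crosses itself exactly twice around each overlapping
lobe and only touches itself at each touch point. `report.json` records the
thresholds, per-stage counts, junction list and the per-merge ledger;
`leaf.xy` is the raw two-column tab-separated coordinate file (the format
ImageJ imports via *File > Import > XY Coordinates*); `coeffs.csv` holds the
first 20 elliptic Fourier harmonics.

Additional subcommands expose the stages individually (`segment` with
`--panel`, `trace`, `junctions`, `concat`, `efa`, `efa-inverse`, `cut`,
`render`); `leafknot --help` lists them.

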