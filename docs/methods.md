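# Methods

This note documents the models, numerical choices and limitations behind
`cmlcells`: a pipeline that segments myeloid-series white blood cells
(WBCs) in ×1000 smear images, measures six morphometric features per
cell, and assigns one of eight maturation outcomes with a fixed threshold
decision tree.

## Coordinate and unit conventions

Images are 8-bit/channel RGB, 0-based, row-major; bounding boxes are
half-open.  All absolute pixel constants (blur sigma, structuring-element
radii, the area and perimeter thresholds of the classifier) are defined
at a reference pixel pitch — the geometry of a 2592×3872 frame at ×1000
magnification.  Crops at that pitch keep scale 1.0; images from other
optics are handled by an explicit user scale factor that multiplies
lengths linearly and areas quadratically.  We deliberately do **not**
infer the factor from image width: a crop has a smaller width but the
same pitch, and width-based scaling would silently corrupt every
absolute threshold.

## Segmentation

**Cell mask.**  Basophilic cells carry more blue than the yellowish
smear background, so the yellow channel of the naive CMYK transform,
`Y = 1 − B/max(R,G,B)` (0 for pure black by convention), separates them
well.  `Y` is enhanced as the arithmetic mean of a linear stretch `L`
and an exact empirical-cdf histogram equalization `H`, rescaled to
[0, 1]; the combination is configurable (`mean`, `sum-clipped`,
`L`-only, `H`-only) because either operator alone is a defensible
reading, and the mean keeps both contributions while staying bounded.  A
constant image is passed through unchanged with a warning (the stretch
is undefined).  Three passes of a 3×3 minimum filter (edge-replicated
borders) suppress bright clutter; Otsu's threshold (256-bin exhaustive
between-class-variance maximization) with dark-side polarity yields the
WBC mask, cleaned by opening (disk r = 5 px), closing (disk r = 10 px)
and hole filling.  Numerically degenerate variance ties in the Otsu
search are resolved arbitrarily; any maximizing cut is accepted.

**Nucleus mask.**  The image is masked to the cell region, converted to
CIELAB, and the a\* channel (nuclei are strongly magenta) is blurred with
a Gaussian of σ = 33 px, min-max normalized over within-cell pixels and
Otsu-thresholded over within-cell pixels only (a global histogram would
be dominated by background).  Polarity defaults to *bright*: magenta
chromatin has high a\*.  Cleanup: closing (10 px diameter), opening
(2 px diameter), hole filling, then an area filter keeping components at
least 25 % of the largest component's area — a relative cutoff, because
no absolute "smaller than a nucleus" area is meaningful across stages.

**Touching cells.**  Marker-controlled watershed: markers are the
regional maxima of the Euclidean distance transform after h-maxima
suppression (h = 5 px), and flooding runs on the Sobel gradient
magnitude of the distance transform, restricted to the foreground.  Thin
components whose maxima are suppressed entirely are re-labeled as their
own regions afterwards so the labels always partition the mask.
Cytoplasm is the pixel-exact set difference cell ∖ nucleus; regions with
no nucleus pixel (red-cell clutter, debris) are flagged and excluded
from classification rather than guessed at.

## Morphometric features

* **Num** — 8-connected components of the nucleus mask.
* **AoN** — total foreground pixel count of the nucleus mask.
* **ACoC** — mean CIELAB b\* over cytoplasm pixels, on the standard
  sRGB/D65 scale (≈ −128..127).  The classifier's color cuts (24/27/30)
  are interpreted on this scale; a configurable affine remap
  (`acoc_scale`, `acoc_offset`) is provided because other 8-bit Lab
  encodings exist in the wild.
* **T1 / T2** — minimum nucleus thickness and minimum convex-hull width.
* **HD** — Hausdorff distance between nucleus-border and cell-border
  pixel sets, symmetric max(h(U,V), h(V,U)) by default (a directed mode
  is available); computed with an early-break algorithm and cross-checked
  in tests against the O(n·m) definition.
* **P1** — border-pixel count of the smaller nucleus part after a
  validated bottleneck split; 0 when no split is performed.

**Bottleneck (T1) detection.**  The ordered outer contour is obtained by
Moore-neighbor tracing.  Candidate point pairs must be at least 10
contour steps apart **and** satisfy a pinch criterion: the Euclidean
chord is at most 0.45× the shorter boundary arc between the points.  The
second clause is essential: for any convex boundary the chord/arc ratio
is at least 2/π ≈ 0.64 (the circle's worst case), so convex shapes and
smooth near-tip pairs on tapered shapes generate no candidates, while a
genuine constriction — spatially close points that are far apart along
the boundary — passes easily.  Ranking only by raw chord length, without
the arc clause, would select degenerate chords near the tips of crescent
shapes and report a spuriously tiny thickness.  Candidates are examined
in order of increasing chord length; a pair is accepted only if the
Bresenham segment between the points contains no background pixel
(pairs whose chord crosses a concavity are rejected).  Contours are
subsampled every 2nd point for the pair search (distance matrices stay
small); the arc length is computed on the full contour.

**T1 semantics.**  T1 is the chord length of the *first* accepted pair
on the original (largest-lobe) mask.  For pinch-free shapes T1 falls
back to T2, making T1/T2 exactly 1 — this is what routes round/oval
nuclei down the tree's regular branch deterministically.

**Split validation and P1.**  The accepted pair's segment is removed
(thickened to 3 px so 8-connectivity cannot leak across it) and the
parts are validated with the area rule as printed: accept iff
area(big) > 3.8 × area(small) **and** area(big) + area(small) > 74 000 px.
A rejected small part is treated as a stain artifact, removed, and
detection re-runs on the remainder (at most 8 retries; each retry
strictly shrinks the mask, so the loop terminates).  Validation governs
only whether a split — and hence P1 — is produced; it never feeds back
into T1.  Without that separation, a symmetric rejected split (e.g. a
kidney-shaped nucleus cut through its notch into two similar halves)
would discard half the nucleus and corrupt the thickness feature.  The
direction of the 3.8× comparison is configurable (`split_comparator`)
because the printed rule and its artifact-removal motivation can be read
both ways; the printed direction is the default.

**Minimum convex width (T2).**  Border pixels are expanded to their four
unit-square corners (so a w×h rectangle measures exactly min(w, h)),
the convex hull is taken, and rotating calipers return the minimum over
hull edges of the farthest vertex-to-edge distance — the smallest
distance between parallel supporting lines.  Tests verify agreement
with a 0.1°-step projection sweep within 0.5 % and rotation invariance.

**Perimeter convention.**  P1 counts foreground pixels with at least one
background 4-neighbor.  This matters because the band-vs-neutrophil cut
(475 px) is expressed in this convention; staircase counting biases a
circle's perimeter about 10 % below 2πr.  A polygonal-length alternative
is available (`perimeter_mode="polygon"`).

**Multi-lobed nuclei.**  T1/T2/HD and the split run on the largest lobe;
`Num` carries the lobation and the classifier short-circuits on it
anyway; AoN remains the total area.

## Classifier

Thirteen stages on (`Num`, T1/T2, T1/HD, `ACoC`, `AoN`, `P1`); every
threshold lives in `ClassifierConfig` and serializes to JSON/YAML.
Boundary semantics: all comparisons are strict as written, so a value
exactly on a cut falls to the non-strict side (T1/T2 = 0.92 → irregular
branch; ACoC = 24 or 27 → MB|PM; AoN = 110 000 or 115 000 → PM|M;
P1 = 475 → N).  The overlap classes exist precisely to absorb borderline
cells, so ties break toward them.  Two interpretation choices are
documented here as the package's own:

* *Notch rewrite* (stages 3–4): for 0.86 < T1/T2 ≤ 0.92 with ACoC < 30
  the notch is ignored — T1 is rewritten to T2 (ratio 1) and the cell
  continues on the regular branch; the rewrite is recorded in the
  classification trace because later stages reuse T1.
* *Notch kept*: the same ratio window with ACoC ≥ 30 is classified MM.
  On the irregular branch stage 11 therefore tests only the lower bound
  (ratio ≥ 0.53); the upper bound is implied by how the branch was
  reached.

Cells missing a feature that the branch actually taken requires (e.g. an
empty cytoplasm on a color stage) yield a ninth outcome,
`unclassifiable`, rather than a forced guess — this keeps downstream
agreement statistics honest.  Totality (every complete vector reaches
exactly one leaf) is property-tested over the whole feature space
including all boundary values.

## Evaluation

One-vs-rest confusion counts per class; sensitivity tp/(tp+fn),
specificity tn/(tn+fp), accuracy (tp+tn)/n, reported in percent with
unweighted macro averages (undefined ratios are reported as `None` and
excluded with a warning).  Cohen's kappa is computed from explicit p₀
(observed agreement) and p_e (chance agreement from the raters'
marginals); κ = 1 when both raters are constant and identical, by
convention.  For binary labels the macro accuracy equals p₀; for more
classes it does not (each disagreement still yields true negatives for
the uninvolved classes), which is why both numbers are reported.  When
two expert labelings form the reference, the "joint" reference is the
subset of cells where the experts agree; disagreeing cells are excluded
and reported — the conservative reading of a two-expert panel.

## Synthetic scenes

The generator renders one leukocyte per scene at reference pitch —
flat-shaded cytoplasm and nucleus over a yellow background with
red-cell-like distractor disks kept clear of the cell, a 1 px optical
blur, and additive Gaussian pixel noise (σ = 3 of 255 by default).
Rendering is a pure function of (spec, seed).  Class conditioning:

| class | nucleus shape | N:C target | intended leaf |
|-------|---------------|-----------:|---------------|
| MB | round, near-centered, r ≈ 0.91·r_cell | 0.82–0.87 | T1/HD > 3.7 |
| PM | oval (0.95, 0.74)·r_cell, offset 0.175·r_cell | ≈ 0.71 | T1/HD ≈ 3.1, ACoC ≈ 36 |
| M  | oval (0.93, 0.65)·r_cell, offset 0.245·r_cell, small cell | ≈ 0.60 | T1/HD ≈ 1.9, AoN < 110 k |
| MM | kidney: disk minus offset bite | 0.44–0.50 | T1/T2 ≈ 0.78 |
| B  | curved band (annular strip + end caps) with a constriction near one end | 0.30–0.33 | T1/T2 ≈ 0.17, P1 ≈ 500–570 |
| N  | 2–4 disjoint lobes on a wide ring | 0.20–0.26 | Num > 1 |

Geometry is solved analytically so each class lands in its classifier
region *after* segmentation, with margin for the known biases of the
pipeline (the σ = 33 blur erodes thin features and shallow concavities;
the minimum filter dilates the cell mask by ~3 px).  Three choices
deserve explanation:

* **Eccentric nuclei for PM/M.**  For a convex nucleus inside a round
  cell, N:C > 0.7 forces T1/HD > 2.1 for *any* placement (the maximal
  Hausdorff distance ≈ 2(r_cell − b) is too small relative to the minor
  axis), so promyelocytes cannot reach the tree's area branch and must
  be separated from myeloblasts by color; myelocytes, with N:C ≈ 0.6 and
  maximal eccentricity, sit just under the 2.1 cut.  The offsets are the
  largest for which the ellipse's farthest point stays ≥ 2 px inside the
  cell (the farthest point of an offset ellipse is not its minor tip).
* **Warm promyelocyte cytoplasm.**  On the standard b\* scale the
  classifier's positive color cuts are reachable only by warm hues —
  no blue has b\* > 27 — so the PM cytoplasm is a pale cream
  (b\* ≈ 39) rather than the basophilic blue of real stains, and its
  nucleus is magenta (high a\*, mild b\*) so that the slight
  under-segmentation of the nucleus does not drag the measured cytoplasm
  mean below the 27 cut.  This trades stain realism for landing in the
  printed thresholds' regions; the affine ACoC remap exists for users
  who prefer to move the scale instead.
* **Band constriction placement.**  The band's bite sits at arc length
  0.63·R_arc from one end: far enough in that the small part's perimeter
  clears 475 px after blur erosion, close enough to the end that the
  3.8× area ratio of the split validation passes.  Both constraints box
  the cut into a window of roughly 120–175 px of band length; the
  placement centers it.

The cell radius for kidney/band shapes is derived *after* rasterizing
the nucleus, so the achieved N:C hits its sampled target (within ±0.05,
warned otherwise); a nucleus that cannot fit its cell raises a geometry
error.

**What passing tests show — and what they do not.**  The closed loop
(render → segment → measure → classify, 240 cells, ≥ 90 % recovered to
the generator class or its adjacent overlap class; mean nucleus Dice
≥ 0.9) demonstrates that the implementation is internally consistent:
the segmentation recovers the masks the features need, the features land
where the tree expects, and the thresholds partition the feature space
as documented.  It does **not** validate the thresholds against clinical
material: real smears have chromatin texture, granules, stain and
illumination variability, touching and overlapping cells, and
out-of-focus debris that the generator deliberately omits.  Performance
figures on synthetic scenes must not be read as diagnostic accuracy.

## Problem sizes and runtime choices

The default test suite renders single-cell scenes of roughly 600–900 px
square and runs the full closed loop once at 40 cells per class — sizes
chosen so the geometry is at reference pitch (the absolute thresholds
stay meaningful) while a complete run stays comfortable on one CPU.
Bottleneck pair search subsamples contours ×2 and caps the candidate
list at 4000 pairs; both are configurable and neither bound is reached
on realistic nuclei.

## Known limitations

* No stain normalization or illumination correction; inputs are assumed
  comparable to the enhancement pipeline's expectations.
* Lobe reconstruction for touching nuclei is out of scope; watershed
  splits cells, not nucleus lobes.
* The bottleneck search assumes the constriction is visible on the outer
  contour; interior holes are filled before analysis.
* `ACoC` thresholds are meaningful only on the standard b\* scale or
  after an explicit user remap.
* Thresholds are fixed constants, not learned; cells outside the
  calibrated geometry (e.g. very small crops at different pitch without
  a scale factor) will stage incorrectly.
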