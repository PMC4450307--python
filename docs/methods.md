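# Methods

## Problem and pipeline

On abdominal ultrasound the appendix appears as a dark (hypoechoic) oval
in the organ region below the bottom fascia line, a bright band that is
frequently broken by acoustic shadowing.  The package reconstructs that
band, restricts attention to the region below it, clusters the pixel
brightnesses there with a distance-based fuzzy ART network, and selects
the darkest, most oval region as the appendix candidate.  Every stage is
deterministic; randomness exists only in the phantom generator's seeds.

Stage order: ends-in contrast stretch → Max-Min binarization → component
labeling + size filter → bottom-boundary extraction → natural-spline gap
bridging → region of interest (ROI) below the curve → fuzzy ART
clustering of the *stretched* ROI brightnesses → quantization →
dark-cluster binarization → erosion → candidate scoring → optional mm
measurement.  Clustering operates on the stretched image because the
stretch is what makes the hypoechoic appendix separable from the
speckle-laden background; candidate mean brightness is measured on the
original image.

## Contrast stretch

The ends-in stretch maps brightness P to

    S = 0                                   P ≤ Min
    S = floor(255 · (P − Min)/(Max − Min))  Min < P < Max
    S = 255                                 P ≥ Max.

Floor rounding is this package's dialect; it keeps outputs in [0, 255]
without a clamp.  Min and Max are chosen from the cumulative histogram:
Min is the smallest occupied brightness whose cumulative fraction reaches
`stretch.low_frac`, Max the largest whose tail fraction reaches
`stretch.high_frac` (defaults 0.01 each).  Zero fractions give the true
extremes; if the rule collapses (Min ≥ Max, possible when both tails land
on the same spike) the bounds widen to the observed extremes.  A constant
image has no usable contrast and raises a degenerate-contrast error,
which the pipeline reports as a structured failure.

Binarization thresholds at the midpoint of the observed extremes of the
stretched image (the literal reading of "Max-Min" thresholding); a pixel
is foreground iff strictly above the midpoint.  Components smaller than
`noise_filter.min_area` = 1500 px are discarded as speckle; the threshold
compares with ≥ (a region of exactly 1500 px survives).  Default
connectivity is 8, which preserves thin diagonal fascia strokes.

## Fascia line and ROI

Fascia components are the size-filtered components whose bounding-box
width is at least `fascia.width_frac` = 0.15 of the image width.  Among
these, only components whose bounding-box bottom lies within
`fascia.bottom_tol_frac` = 0.15 of the image height from the lowest one
form the *bottom* line: without this second filter an upper fascia band
would supply per-column boundary pixels inside the bottom band's gaps and
silently close them, and gap bridging would never trigger.  The bottom
boundary is then the per-column lowest fascia pixel; columns with no
bottom-line pixel are exactly the gaps.

Boundary points are thinned to every `fascia.knot_stride` = 8th column
(always keeping the last point) so the spline smooths per-column speckle
jitter instead of interpolating it, and a natural cubic spline is fitted:
zero second derivative at both end knots, C1/C2 continuity at interior
knots, exact interpolation of the knots.  The spline is evaluated by the
standard piecewise-cubic machinery; tests verify it against an
independent tridiagonal solve of the knot-curvature system.  Bridging
rasterizes the curve (rounded per integer column, clipped to the image)
into the mask, which reconnects the band without removing pixels.

The ROI is every pixel more than `roi.margin_px` = 2 rows below the
curve; outside the knot span the curve extends horizontally at the
end-knot height, because the natural spline's own linear extrapolation
can dive off-image on a steep end segment.

## Fuzzy ART clustering

Each ROI pixel is presented once, in row-major order, as a normalized
brightness x = P/255.  Each committed cluster j holds a scalar prototype
w_j.  The rules:

* distance:   O_j = |w_j − x| / β_max
* winner:     minimum O_j, ties to the lowest index
* vigilance:  resonate iff w_j = x exactly, or min(w_j, x)/β_max > ρ
* learning:   w′ = α·min(x, w) + (1 − α)·w

A pixel tries clusters nearest-first and resonates with the first that
passes vigilance; otherwise it founds a new cluster at its own value
while fewer than `fuzzyart.max_clusters` exist, and past that cap it is
assigned to the nearest prototype without learning.  Defaults: ρ = 0.85,
α = 0.5, β_max = 1.0, cap 16.

The exact-match clause in the vigilance test is a deliberate design
choice.  Under the min-based test alone, any pixel with x ≤ ρ can never
resonate with any cluster, so a run of identical dark pixels would found
identical clusters until the cap is exhausted, wasting the entire
capacity on one brightness; treating an input identical to a prototype as
maximally similar restores the natural behavior that identical inputs
share one cluster.  Distinct dark pixels still always found new clusters
while capacity remains — a property of this vigilance form worth knowing:
with the default ρ the cluster budget fills with the first ~16 distinct
brightnesses seen, after which the network acts as a fixed
nearest-prototype quantizer.  That behavior is stable, order-determined
and reproducible, and on stretched ultrasound-like content it reliably
places at least one prototype in the dark range occupied by the appendix.

One presentation epoch is used: the update rule is contractive and a
second epoch changes assignments only marginally while doubling cost.
Prototypes are reported on the 0–255 scale with round-half-up.

## Candidate extraction

Clusters whose prototype is at or below the `extract.dark_quantile` =
0.25 quantile of prototype values are binarized as "dark".  The dark mask
is eroded with a square structuring element of side 2·`erode_radius`+1 =
3, `erode_iterations` = 2 times; erosion removes isolated dark speckle
(which is spatially independent, so the probability of a 5×5 all-dark
window is negligible) while the solid appendix survives.  Surviving
regions of at least `extract.min_area` = 200 px are scored by

    score = ellipticity · (1 − mean_brightness/255),

where ellipticity = region area / area of the second-central-moments
equivalent ellipse.  Both factors live in roughly [0, 1]; a compact oval
scores near 1 on the first factor while an irregular ascites blob scores
low, which is what lets the method discriminate ascites of similar
darkness.  Ties go to the larger region.

Erosion is treated as a selection device, not a delineation device: the
winning eroded region is grown back by dilating with the same structuring
element, clipped to the dark mask and to the component connected to the
winner (a seeded opening).  This restores the organ's true outline — a
plain post-erosion mask under-covers a smooth ellipse by the erosion
depth, capping overlap with truth at ≈ 0.88 IoU — without flooding into
speckle that touches the region only through thin chains (full
connected-component reconstruction was evaluated and rejected: at
realistic speckle the dark mask can percolate and the component then
covers half the ROI).  Features are re-measured on the final mask.  If no
region survives, the pipeline returns a structured failure record, the
package's analogue of the method failing on a low-contrast image.

The minor axis of the equivalent ellipse times the pixel spacing (when
known, e.g. from DICOM PixelSpacing) gives an approximate outer diameter
in mm.  No diagnostic decision is made; the clinically used 6 mm
threshold is left to the user.

## Phantom generator

Phantoms emulate the scene the pipeline expects: a mid-gray background
(110), two bright fascia bands (brightness 200; the bottom one at row 160
with a configurable gap), a dark rotated-ellipse appendix (brightness
~30) below the bottom band, and optionally a dark irregular ascites blob
(a 24-vertex radial polygon with ±45 % radius jitter, brightness ~35)
acting as the false-positive distractor.  The composited scene is
multiplied by log-normal speckle (σ = 0.15 by default) and clipped to
[0, 255]; an optional contrast factor compresses the scene toward
mid-gray to emulate low-contrast failure cases.  Ground-truth masks are
exact by construction, and a given seed fixes the raster bit-for-bit.

What the phantoms do *not* model: spatially correlated Rayleigh speckle,
depth-dependent attenuation and focusing, curved or oblique fascia,
partial-volume boundaries, neighboring bowel gas.  Passing the phantom
battery therefore demonstrates the pipeline's internal correctness and
its geometric discrimination logic, not clinical performance.

The documented default battery is 50 phantoms: gap widths cycling through
0–60 px, the ascites distractor present in every second phantom, speckle
σ = 0.15, and seeded jitter of the appendix/ascites geometry (position,
axes, angle, brightness) and the gap position, with the distractor placed
so it never touches the appendix.  Robustness to other speckle levels is
exercised separately (σ = 0 and heavier noise in the tests), keeping the
battery's conditions fixed and comparable.

Extraction on a phantom counts as a success when the candidate mask
reaches IoU ≥ 0.5 against the ground-truth appendix mask — a computable
stand-in for expert judgment of "correctly extracted".

## Numerical choices and degenerate inputs

* Luma conversion of color inputs: ITU-R BT.601 weights (0.299, 0.587,
  0.114), rounded half-up.  Rasters deeper than 8 bits are linearly
  mapped from their observed range onto [0, 255].
* Region labels are assigned in raster-scan order of each component's
  first pixel, making labelings comparable across implementations.
* Prototype and curve rasterization rounding: round-half-up (prototypes,
  spline ordinates); Eq-style stretch uses floor as stated above.
* Constant image → structured failure at the stretch stage; image with no
  wide bright component → structured failure at the fascia stage;
  appendix-free image → structured failure at the extract stage.  None of
  these raise out of `run_pipeline`.
* All floating-point behavior is deterministic; re-running any stage on
  the same input is bit-identical.

## Problem sizes

Default phantoms are 512×420 px with a ~130k-pixel ROI; a full pipeline
run takes roughly a second on one core, and the 50-phantom battery about
a minute.  These sizes match the scale of typical exported ultrasound
stills and keep the validation suite quick to run.

## Known limitations

* The cluster budget is seeded by the first distinct ROI brightnesses
  (see above); on images whose upper ROI rows are unrepresentative of the
  full brightness range, the dark quantile cut can be mis-placed.
* The ellipticity score assumes the appendix cross-section is roughly
  convex; a strongly curved, retrocecal appendix section may score low.
* The bottom-line selection assumes the bottom fascia segments' lowest
  rows agree within 15 % of the image height; a steeply sloped fascia
  would need a larger `fascia.bottom_tol_frac`.
* Pixel spacing is taken as isotropic from the first DICOM PixelSpacing
  component; anisotropic probes are not corrected for.
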