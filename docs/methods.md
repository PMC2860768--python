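# Methods

## The measurement problem

A QLF capture is a single grayscale image in which demineralized enamel is
darker than the surrounding sound enamel. The quantity of clinical interest is
the *percent fluorescence loss* of a lesion relative to the sound fluorescence
the same pixels would have shown — a counterfactual that must be reconstructed
from the sound tissue around the lesion. The user supplies that context as a
polygon ROI whose edges lie on sound tissue and follow the lesion outline.

## Sound-enamel reconstruction

### Coordinate and rasterization conventions

Pixels are indexed 0-based with x = column, y = row and centers at integer
coordinates. A polygon (real-valued vertices allowed) is rasterized into

* **interior** pixels: centers inside the polygon under the even-odd rule,
  which handles non-convex lesion outlines deterministically;
* **border** pixels: every pixel any edge passes through, computed by
  supercover traversal (exact corner crossings add both adjacent pixels).
  Supercover closes diagonal gaps, so walking from any interior pixel along
  its row or column always meets a border pixel before leaving the polygon —
  every interior pixel is guaranteed its four anchors. A pixel that is both
  is classified as border.

Border intensities are pre-smoothed as 3×3 window means (windows clipped at
the image boundary — the mean is over the available pixels; no intensities
are invented outside the image). Reconstruction errors are proportional to
anchor errors, so smoothing the anchors directly reduces the variance of
every interior estimate.

### Two-step interpolation

For interior pixel M with row anchors g (left), h (right) and column anchors
e (top), f (bottom):

* step 1: L_M(x) = L_g + (L_h − L_g)(X_M − X_g)/(X_h − X_g);
* step 2: the same horizontal rule is evaluated at e and f on their own rows,
  giving L_e(i), L_f(i); the residuals ΔL_e = L_e − L_e(i),
  ΔL_f = L_f − L_f(i) are interpolated vertically and added:
  L_M(i) = L_M(x) + L_M(y).

When step 1 is applied *at a border pixel* (e or f), the anchors are the two
endpoints of the contiguous run of border pixels that contains it on its row.
For an axis-aligned rectangle the top and bottom edges are single runs whose
endpoints are the rectangle corners, so this rule reproduces the classic
rectangle algorithm (corner-based edge interpolation) exactly; for a run of
one pixel (a steep edge) the interpolated value is the pixel's own value and
the residual vanishes. The rule is exact on affine fields, preserving the
scheme's defining property: **any intensity field affine in (x, y) is
reconstructed without error**, for both the rectangle and polygon forms
(verified to 1e-9 relative in the test suite).

Two forms are exposed deliberately. `interpolate_rectangle` is the faithful
reference form of the original algorithm — axis-aligned, raw (unsmoothed)
edge intensities — and serves as the oracle target for a scalar transcription
of the equations. `interpolate_polygon` is the production form: arbitrary
simple polygon, smoothed anchors.

### Loss maps

ΔL_M = L_M(i) − L_M with L_M the *raw* observed intensity (smoothing applies
only to border anchors). Percent loss is 100·ΔL_M / L_M(i) — loss relative to
the local reconstructed sound value, the standard QLF ΔF convention, which
makes the metric invariant to global intensity scaling (and hence to the 8-
vs 16-bit question; intensities are kept on their native integer scale).
Negative values (pixel brighter than reconstruction: remineralization,
specular highlights) are retained in the maps but never selected as maxima.
Pixels whose reconstructed sound value is ≤ 0 are flagged invalid.

## Robust maximum loss

A single-pixel maximum is fragile: one spuriously dark sensor pixel (a "cold
spot") reads as a huge loss. Candidates are ranked by percent loss
(descending, ties broken row-major). For each candidate the mean percent loss
of its 3×3 neighborhood (interior pixels only, window clipped at the ROI
boundary) is computed; if (candidate − mean)/candidate exceeds
`rel_tolerance` the candidate is rejected and the search moves down the
ranked list. The accepted candidate's neighborhood mean is reported.

* `rel_tolerance` (default **0.20**): scale-free and conservative — a genuine
  smooth maximum exceeds its 3×3 mean by a few percent at most, while an
  isolated spike exceeds it by nearly its own magnitude. Whether the original
  "significant difference" check was a fixed margin or a test is not
  determinable; the margin is exposed as a parameter.
* The search iterates down the full ranked list rather than stopping at the
  second-largest value: several cold spots can coexist, and with a single one
  the behavior is identical. The exhaustion fallback (last candidate's mean,
  with a warning) is defensively coded but unreachable: the lowest-valued
  pixel's neighborhood mean can never lie below its own value.
* `area_threshold` (default **5 %** loss) defines the lesion-area count, a
  conventional cutoff for reporting lesion extent.

The reported robust maximum is a 3×3 mean and therefore sits slightly below
the true profile peak (≈ 0.4–0.6 % absolute for the default phantom
geometry); this is the price of the noise immunity and is part of the metric's
definition, not an estimation error to be corrected.

## Depth calibration

The packaged reference dataset is six paired observations from demineralized
extracted molars: maximum percent fluorescence loss (image analysis) against
largest lesion depth in µm (polarized-light microscopy of sections). Percent
loss Y is regressed on depth X by OLS:

    Y = 0.32·X + 0.17,  r = 0.9696,  t(4) = 7.93,  F(1,4) = 62.86

p-values come from the exact t and F distributions; F = t² is an algebraic
identity of simple regression, so both tests share the single two-tailed
p = 0.0014 (reporting two marginally different values, e.g. .0014 vs .0013,
can only arise from rounding intermediate statistics). The regression is
deliberately fitted in this orientation — loss on depth — because it is the
orientation consistent with all the reference statistics; depth for a new
measured loss is then obtained by inverse prediction,

    x̂ = (y₀ − b)/m,   x̂ ± t_{α/2, n−2} · (s/|m|) · √(1 + 1/n + (x̂ − x̄)²/Sxx),

the standard single-observation calibration interval (default 95 %). A
measured loss below the intercept yields a negative estimate, returned with
an out-of-range warning rather than clipped.

## Synthetic phantoms

`generate_phantom` renders: a smooth sound field (constant; affine with
default base 170 intensity units and gradients 0.2/0.15 per pixel — typical
8-bit sound-enamel levels with a mild illumination trend; or a quadratic dome
emulating natural crown curvature), an elliptical lesion with a cosine-taper
radial profile (smooth, compactly supported, unambiguous peak; default radius
15 px, peak 25 %), additive Gaussian sensor noise (default σ = 1 intensity
unit), and optional single-pixel hot/cold spots. The lesion is
multiplicative — observed = sound · (1 − loss/100) — so the percent-loss
ground truth is exact by construction even on curved fields. A suggested
octagonal ROI encloses the lesion with a 4-pixel sound margin.

What the phantoms do *not* emulate: enamel light scattering and translucency,
surface staining, moisture, specular reflections, spatially correlated noise,
and irregular lesion margins. Passing phantom tests therefore demonstrates
the correctness and noise robustness of the *algorithm*, not the physical
accuracy of QLF on real teeth.

Problem sizes used by the tests and the acceptance script — 80×80 phantoms,
20 seeded replicates with peaks 10–30 %, 100 random affine/polygon cases at
24×24, 50 random rectangle-oracle cases at 16×16 — are large enough that the
measured bias (≈ −0.5 %) and RMSE (≈ 0.6 %) of peak recovery are stable to
the seed, while the whole suite runs in seconds.

## Numerical and design notes

* Fire LUT: the widely used 32-control-point "Fire" table, linearly
  interpolated to 256 entries; percent values are clipped to
  [0, max_percent] and mapped linearly to indices 0–255 (entry 0 black,
  entry 255 white). Pixels outside the ROI render black; a vertical scale
  bar is appended.
* Color images are rejected, not converted: any channel-mixing rule would
  alter loss values invisibly.
* Ties in the maximum search are broken by row-major order, making the
  metrics bit-reproducible for identical inputs.
* Integer-valued images round-trip losslessly through save/load at their
  source bit depth.

## Known limitations

* The reconstruction is linear; on strongly curved sound fields it inherits a
  bias bounded by the field's deviation from local planarity across the ROI
  (≈ 3 % peak error for the default dome phantom). Higher-order
  reconstructions are deliberately out of scope.
* The calibration rests on six in-vitro pairs from smooth-surface lesions;
  extrapolation beyond its depth range (≈ 38–99 µm) widens the inverse
  interval rapidly and is flagged, not forbidden.
* Single-image analysis only: no longitudinal registration, lesion-volume
  integration, or multi-tooth batching.
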