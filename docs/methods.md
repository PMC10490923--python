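# Methods

## Optical model

The sensing column is modelled as three homogeneous layers with parallel
planar interfaces: outer medium (air) of thickness h₀ above the fluid,
fluid of depth L, outer medium of thickness h₁ between the well bottom and
the measurement plane. A ray leaving the on-axis source at angle θ₁
refracts to θ₂ = arcsin(n₁ sin θ₁ / n₂) at the fluid surface and back to
θ₁ at the fluid bottom (parallel interfaces). Accumulating the lateral
offsets h₀ tan θ₁ + L tan θ₂ + h₁ tan θ₁ and back-projecting the exit ray
onto the optical axis gives the apparent source distance

    I(L) = h₀ + h₁ + L · tanθ₂ / tanθ₁

which is first-degree in L and reduces to the true distance h = h₀+L+h₁
when L = 0 or the indices match. Two parameterizations of a depth sweep
exist and both are exposed:

* **fixed h₀, h₁** (`OpticalStack` varied in L): the column grows with L
  and I grows with slope tanθ₂/tanθ₁ < 1 — always less than the true
  distance;
* **fixed well filling** (`fill_stack`: h constant, h₀ = h − h₁ − L):
  I = h − L(1 − C₂/C₁), strictly decreasing for a fluid denser than the
  surroundings. This is the physical scenario — the source appears closer,
  and hence larger, as the well fills — and the one monotonicity tests
  use. The relationship inverts for a fluid rarer than the surroundings.

θ₁ is a free parameter because the source emits in all directions; any ray
intersecting the surface yields the same first-degree structure. The
default is 5° (small-angle regime of a distant small source); in the
paraxial limit tanθ₂/tanθ₁ → n₁/n₂ and I → h₀ + h₁ + L·n₁/n₂, the
classical apparent-depth formula, which the implementation reproduces to
< 1e-7 relative at θ₁ = 0.1°.

The model deliberately ignores refraction in the plate bottom, meniscus
curvature, and camera lens optics. Those enter empirically: through the
calibration layer (which never assumes the analytical slope) and through
the synthetic response model below. The closed form is certified against
`trace_ray_oracle`, an explicit segment-by-segment construction sharing
no algebra with it beyond Snell's law; agreement is at machine precision
(≈7e-16 over a 1000-point grid, vs. the 1e-9 requirement).

Angles are radians internally; the CLI accepts degrees. Apparent size
follows a pinhole projection, perimeter = π·d·s/I with d the source
diameter and s the pixel scale obtained by imaging a ruled slide at known
distances.

## Synthetic well response

`WellResponseModel` encodes the perimeter-vs-volume curve of one well as
four regimes. Defaults describe a 24-well plate well (~3.5 ml) of water;
every breakpoint and slope is configurable.

| parameter | default | meaning |
| --- | --- | --- |
| v_film | 0.5 ml | film formation in a dry well; scatter below |
| v_A | 0.4 ml | first coherent reading (pre-moistened well) |
| v_stable | 1.0 ml | meniscus stable; start of linear band |
| v_B | 2.8 ml | onset of meniscus inversion |
| v_C | 3.4 ml | overflow; plateau beyond |
| p0 | 260 px | perimeter at v_A |
| s_A, s_lin, s_inv | 40, 120, 360 px/ml | ramp, linear, inversion slopes |
| tilt_bias | 0 px | uniform positive offset of a tilted plate |
| opacity | 0 | background lift + spot dimming of cloudy fluids |

Region A is a quadratic ramp whose slope grows from s_A at v_A to s_lin at
v_stable, making the curve C¹-continuous at the linear join; regions B and
C are linear; region D is exactly constant at the v_C value. Readings are
valid for v ≥ max(v_film, v_A): with the defaults a dry well starts
reading at 0.5 ml, and lowering v_film to v_A models a pre-moistened well
reading from 0.4 ml. Dry-well scatter is drawn uniformly over a wide
perimeter band — deliberately information-free. The linear band
(1–2.8 ml) and the overall perimeter scale were chosen to fill a 480 px
frame without clipping at overflow; the region-A curvature and region-C
slope are illustrative magnitudes, not fitted to any measured well.

Scenes are rendered as area-averaged (3× supersampled) ellipses of the
requested Ramanujan perimeter and axis ratio, plus seeded Gaussian sensor
noise. Occlusion is a concentric dark disc — solid contents such as an
organoid resting mid-well — which masks up to half the spot area while
leaving the outer boundary measurable; this is the occlusion regime the
robustness claims refer to. A thin occluding bar crossing the rim is a
different, harsher case and is handled by morphological closing in the
detector. Fill sequences perturb each step's perimeter by a disturbance
that decays geometrically (amplitude σ_d·r^t, defaults 12 px and r = 0.5),
emulating the surface sloshing after fluid is dispensed.

What the generator does **not** emulate: caustics and meniscus-edge
optics, lens distortion, uneven illumination, compression artifacts, and
secondary reflections. Passing tests therefore demonstrate the pipeline's
correctness and its robustness to noise/occlusion/transients as modelled,
not performance on any particular physical rig.

## Detection

Frames are converted to grayscale by Rec. 601 luminance, thresholded
(fixed 200 by default — the clear-water setting — or Otsu), closed with a
2 px disc so thin dark streaks do not sever the blob, and labelled. Among
components ≥ 50 px², the one whose centroid is nearest the image centre is
selected (exact ties: larger area, then topmost-leftmost bounding box;
an optional `center_weight` trades centrality against size instead). The
component's outer boundary is extracted at sub-pixel resolution by
marching squares and an ellipse is fitted by least squares; the reported
measurement is the Ramanujan-II perimeter π[3(a+b) − √((3a+b)(a+3b))] of
the fitted ellipse (relative error < 1e-4 vs. the elliptic integral for
a/b ≤ 3). The fitted-ellipse perimeter, not the raw arc length, is the
signal: a least-squares fit degrades gracefully when boundary pixels are
missing or ragged, which is what makes the method robust to occlusion and
noise. Raw contour area is kept as a diagnostic. Per-frame failures
(blank frame, no component, degenerate fit) are flagged readings, not
exceptions, so streams keep flowing.

Cloudy fluids (oil) lift the background and dim the spot; the fixed
water threshold then finds nothing and must be adjusted (or switched to
Otsu), after which the principle holds — the synthetic `cloudy_scene`
reproduces exactly this behavior.

## Stabilization

A reading is accepted when the rolling buffer (default 10 frames) is
full, all slots hold valid readings (`min_valid_fraction` = 1.0), and the
sample (n−1) standard deviation of the values is ≤ 2 px. The accepted
value is the buffer mean. Sample rather than population deviation is a
deliberate choice (slightly conservative); acceptance repeats every frame
while the stream stays stable, and consumers deduplicate per dispensing
step by keeping the last acceptance. The implementation is checked
frame-for-frame against an independent brute-force restatement of the
rule on randomized settling sequences.

## Calibration

Curves map perimeter → volume directly (the evaluation direction),
avoiding numerical inversion of a perimeter(volume) fit; on monotone data
the two directions agree. Perimeters are standardized (centred on the
mean, scaled by the standard deviation — for the exact 2-point fit, by the
half-spread) before least squares for conditioning, and the
standardization is serialized with the coefficients, so a saved JSON curve
is self-contained. Monotonicity over the fitted perimeter range is
checked on a 512-point grid at fit time and violations raise
`MonotonicityWarning` — typically a small wiggle of the order-4 fit at the
extreme top of the inversion region. Percentage error is relative to true
volume; the absolute error in ml is reported alongside. Error statistics
pool per-measurement errors across runs (mean and sample deviation over
the pooled errors, not over run means).

The six-point auto-selection picks, in each of the low/mid/end regions,
the measurements closest to the 25th and 75th percentile of the region's
volume span; manual point lists are always accepted.

## Canonical experiment and problem sizes

`experiments.measure_fill_run` renders a 25-step fill (0.5 → 3.4 ml,
14 frames per step at 480×480 px, noise σ = 5, axis ratio 0.9,
disturbance 12 px with r = 0.5) through the full chain — roughly 350
frames, a few seconds of compute — and `experiments.error_table` fits all
calibration families on the first run's six auto-selected points and
evaluates them on the held-out steps. Under these conditions every step
yields a stable reading, the order-5 fit recovers held-out linear-band
volumes to well under 5% mean error, and the characteristic ordering
holds: errors decrease with polynomial order, with clearly diminishing
returns after order 4, and the 2-point line is several times worse than
any polynomial once evaluated over the full range while being excellent
inside the linear band. These sizes were chosen as the smallest that
exercise all four response regions with settled readings at every step.

## Numerical and degenerate-input conventions

* Pixel coordinates: origin top-left, x right, y down; ellipse centers
  are (x, y), contours (row, col).
* Otsu on a constant image yields an empty mask; fixed threshold 0 yields
  a full mask.
* Ellipse fits require ≥ 5 non-collinear points; the fitted a ≥ b is
  enforced by axis swap, rotation wrapped to (−π/2, π/2].
* Total internal reflection raises a dedicated error; it can only occur
  fluid→air, i.e. for exit angles beyond the critical angle, which the
  forward geometry never produces from a valid θ₁.
* Rendering clips to [0, 255] after noise; determinism is guaranteed by
  per-frame seeds derived from the run seed via `SeedSequence`.

## Known limitations

* The analytical optics is 2-D and meridional; skew rays, plate-bottom
  refraction and meniscus curvature are handled only through calibration
  and the empirical response model.
* Frame sources are directories or single images; live-stream and video
  sources plug in through the `iter_frames()` protocol but are not
  shipped.
* Calibration transfer across tilted plates is out of scope: a tilt shows
  up as a positive bias and needs its own calibration.
* The dry-well regime is detected only implicitly (scatter never
  stabilizes); there is no explicit dry-well classifier.
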