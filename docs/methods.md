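# Methods

## Kinematic model

The organ is a two-dimensional beam of width `W` clamped at the base. Its
state is a Lagrangian set of material markers carrying arclength `s` and
signed curvature `C` (left-bending positive). Three ingredients define the
dynamics, all purely kinematic — no stresses, turgor or elasticity:

1. **Steady apex-anchored growth.** The midline's relative elemental growth
   rate depends only on apex distance `s' = L(t) − s`:
   `Ė(s') = (Ė_max/2)(1 − tanh((s' − L_gz)/λ))`. The profile rides with the
   apex, so a growth zone of constant length propagates.
2. **Localised oscillating differential growth.** The two lateral faces
   grow at `Ė ± δĖ/2`, with
   `δĖ = δE_max · sech²((s' − s_bz)/L_bz) · sin(2πt/T)`. The sech² envelope
   is the (normalised) derivative of the mean sigmoid; with `s_bz = L_gz`
   (the default) its peak coincides with the drop of the mean rate, which
   is what the time-averaged profiles of real rachis data show.
3. **Curvature driven only by differential growth.** The face arclength
   elements of a beam satisfy `ln(δs⁺/δs⁻) = 2·artanh(CW/2)`;
   differentiating in time with curvature advection neglected gives
   `∂C/∂t = (δĖ/W)(1 − (CW/2)²)`. Advection is negligible because the
   nutation period (hours) is much shorter than the elongation time scale
   (days); curvature dilution by mean growth is likewise ignored, as
   dilution and growth-induced curvature creation compensate.

Angles and positions are reintegrated from the base at every output time
(`θ = θ_base + ∫C ds`, trapezoid; positions by arclength quadrature of the
unit tangent).

### Parameters (defaults)

| name | meaning | default | basis |
|---|---|---|---|
| `Edot_max` | plateau mean elongation rate | 0.05 h⁻¹ | order of magnitude typical of growing aerial organs; not a measured constant |
| `L_gz` | growth-zone length from apex | 50 mm | length scale of the measured mean-rate profile |
| `lambda_gz` | sigmoid transition width | 15 mm | chosen so the rate falls below 1 % of the plateau before 100 mm, where growth is undetectable |
| `dE_max` | differential amplitude | 0.01745 h⁻¹ | amplitude-relation inversion of a 25° apex swing (see below) |
| `L_bz` | bending-zone envelope width | 15 mm | matched to `lambda_gz` (envelope = derivative of the sigmoid) |
| `s_bz` | envelope centre | `L_gz` | envelope peaks where the mean rate drops |
| `T` | nutation period | 2.5 h | middle of the observed 2–3 h range |
| `W` | beam width (=2R) | 3 mm | typical rachis diameter |
| `L0` | initial length | 150 mm | organ long enough to hold the whole growth zone plus a mature zone |

### Numerical choices

* **Time integration**: explicit Euler at `dt = T/500`; segment lengths are
  updated by the exact exponential `exp(Ė·dt)` at the segment-midpoint rate.
  Halving `dt` moves the final apex position by well under 0.1 % (tested),
  and the no-bending length trajectory matches an independent continuum
  quadrature along characteristics to < 0.1 %.
* **Initial curvature**: the simulation starts from the *steady
  oscillation* state `C₀(s') = −(δE_max·T/2πW)·g(s')` rather than from a
  straight organ. Nothing in the model relaxes curvature, so a straight
  start keeps a permanent DC curvature offset and the organ would oscillate
  one-sidedly; real nutation oscillates about a rectilinear state. A
  `straight` option remains for studying that transient.
* **Markers**: 301 Lagrangian markers (0.5 mm initial spacing); Eulerian
  kymographs are produced by per-frame linear interpolation, with the
  apex-distance convention flagged on every kymograph (`axis_origin`).

## Camera projection

The bending plane is horizontal: a top view sees the true midline, a side
view the orthogonal projection (image coordinate = x). Apparent rates are
computed from the projected lengths of *material* segments of the observed
face polyline — the same estimator the image-correlation measurement uses —
so `apparent = material + geometric` holds exactly cell by cell
(`geometric = d/dt ln(projected/true length)`). The side camera observes a
lateral face, so the material term carries the `δĖ/2` modulation at period
`T`, while the geometric term, an even function of θ, oscillates at `T/2`.
This frequency split (2:1) is the signature used throughout. Segments
within numerical precision of perpendicular are masked, not errors.

## Synthetic data

The generator emulates what the study's acquisitions deliver: top views
every 2.5 min, side views every 1 min; node markers at fixed material
coordinates with Gaussian detection jitter and Bernoulli dropout
(fluorescent dots fade, split and get occluded); speckle-textured frames
whose texture lives in material coordinates, so features advect with the
tissue and stretching dilutes summed pigment intensity per pixel, as for
real painted pigments. A single seed fans out to independent substreams per
product. What passing tests do *not* show: robustness to leaflet occlusion
beyond the dropout model, non-planar (3-D) nutation, lighting drift, or
amplitude modulations of nutation slower than the record — none of which
the generator emulates.

## Measurement chain

* **Midline**: organ thresholding (Otsu by default), per-column unweighted
  centroid of the masked band (immune to the asymmetric pigment texture),
  then a moving median (2 mm default). Curvature by sliding-window
  algebraic (Taubin) circle fits — unbiased at small arcs — on a 10 mm
  window; window extent is measured on a lightly smoothed copy of the
  polyline because raw point jitter inflates polyline arclength. Collinear
  windows return curvature 0.
* **Node tracking**: per frame, an order-preserving minimum-displacement
  matching (dynamic programme with a skip penalty of one `max_disp`)
  embodies the conservation / ordering / displacement rules: two dots can
  never swap. Gaps ≤ 3 frames are closed; longer gaps are flagged for
  manual correction, never guessed.
* **Segment elongation**: centred log-derivative of inter-node distances,
  one-sided at record edges; optional 3×3 mean-then-median smoothing (for
  noisy data only — the filters mix neighbouring segments).
* **Image correlation**: 1-D normalized cross-correlation of band-averaged
  intensity profiles between frames ~9 min apart, parabolic sub-pixel peak
  (skipped on exact matches, where a parabola through asymmetric
  neighbours would drift off zero), strain by local linear regression of
  the displacement over ~32 mm, light 0.2 h time smoothing. The lag and
  smoothing windows stay below a quarter of the fastest (`T/2`)
  oscillation so the signal is not attenuated; the regression span
  averages the sub-pixel errors of several windows. Settings were fixed by
  synthetic-recovery performance at the observed ~25° nutation amplitude.
* **Envelopes**: per-position analytic-signal magnitude after mean
  removal, smoothed over a quarter of the FFT-dominant period; records
  shorter than 3 periods are an error, not a silent estimate.
* **Apex-frame averages**: every kymograph cell is rebinned to its apex
  distance and averaged per 15 mm bin. The bin width equals the sigmoid
  transition width `λ` — half the ~3 cm mature inter-node spacing — so the
  transition stays resolved (two bins per `λ` would already be marginal at
  3 cm bins).

## Wavelet analysis

Continuous wavelet transform with the second-order complex-Gaussian
('cgau2') mother wavelet; energy `= |C(a,b)|²`, time-aggregated by the mean
outside the cone of influence (`√2·a` samples from each edge) and
normalized per position to unit maximum (a global option exists; the
per-position view is the default because it exposes the mode layout
independently of where the signal is strong). The scale→period constant is
calibrated so that a pure sinusoid's aggregated energy peaks at its own
period — the wavelet's nominal centre frequency would misplace it by ~11 %
uniformly across scales, since the aggregated energy folds in the CWT's
scale normalization; the ratio of two dominant periods is unaffected by
this choice, but absolute periods matter for reporting. Periods are read on
a logarithmic grid (32 voices per octave). Mode counting: distinct
dominant-period plateaus separated by more than one grid step, each
covering ≥ 10 % of positions.

## Inference

* **Profile fits**: weighted least squares (√count weights) of the sigmoid;
  bins must number ≥ 8 and show actual decay, otherwise the fit errors out
  instead of silently extrapolating. CIs by bootstrap over bins (200
  resamples, seeded). The differential envelope is then fitted with its
  shape *fixed* to the derivative of the fitted sigmoid — one amplitude,
  closed-form weighted projection.
* **Amplitude relation**: `δE_max = A·R/(T·L_bz)` inverts the chain
  "differential growth over one period → curvature → apex deviation". It is
  an order-of-magnitude estimate: the exact small-amplitude closed form of
  the model is `A = (δE_max·T/2πW)·∫g ds'` (`∫g ≈ 2L_bz`), i.e. the
  relation drops a factor ≈ 2π. The package keeps the prefactor-free form
  (as a single flagged constant, `EQ6_PREFACTOR`) because that is the form
  whose inversion of a 25° swing (~0.017 h⁻¹) lands on the order of the
  mean growth rate — the scientific point of the estimate — and verifies
  both facts by simulation: the measured swing matches the exact closed
  form to a few percent and the inversion to its order of magnitude.
* **Wavelet-map fit**: Frobenius distance between per-position-normalized
  energy maps of observation and forward simulation (simulate → side-view
  apparent rate → energy map), coarse 4ⁿ grid then Nelder–Mead, parameters
  measured beforehand (T, geometry, mean-growth profile) held fixed. A flat
  objective raises an error rather than reporting an arbitrary estimate.
  Normalization makes the objective invariant to global energy rescaling.
* **Contraction test**: minimum over position and phase of the worse face
  rate `Ė − δE_max·g/2`, on a 2001-point grid. With the envelope matched to
  the sigmoid the face rate factorizes as
  `((1−tanh u)/2)·(Ė_max − δE_max(1+tanh u))`, so `δE_max > Ė_max` is
  *sufficient* (at the envelope centre `Ė = Ė_max/2`, `g = 1`), but the
  exact threshold on a finite organ is `Ė_max/(1+tanh(u_max))` — about half
  `Ė_max` for a long organ, reached with exponentially small margin in the
  basal tail where both rates vanish. The test reports the honest grid
  minimum; the brute-force scan and the analytic factorization agree in the
  tests.

## Problem sizes

Default runs use five nutation periods (12.5 h) at `dt = T/500` with 301
markers; wavelet maps use 40 positions × ~84 periods on 4×-subsampled time
series; the wavelet-map fit runs a reduced forward model (three periods,
121 markers, 24 positions, 12 voices per octave), which recovers self-fit
parameters essentially exactly while keeping a full fit under ten seconds.
Recovery studies use 20 noise realizations. These sizes resolve every
structure the analysis relies on; nothing changes qualitatively at higher
resolution (convergence tested).

## Known limitations

Planar kinematics only (no torsion, no 3-D nutation ellipses); no mechanics
— the model cannot say *why* differential growth oscillates, only what
kinematics it implies; the amplitude relation is deliberately
order-of-magnitude; node tracking assumes the first frame shows every
marker; the image-correlation estimator assumes a near-horizontal organ
band within the frame and breaks near the apex tip (masked, and excluded
from comparisons within 10 mm of the apex); slow modulations of nutation
amplitude are outside the model.
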