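# Methods

## Scope and coordinate conventions

`tensiledic` analyses uniaxial tensile tests of soft, speckle-painted
specimens filmed from the front. All image quantities use 0-based pixel
coordinates, x rightward (array axis 1), y downward (array axis 0); the
loading axis is y. Geometry is entered in millimetres (as read off the
dog-bone mould) and converted to SI internally; stresses are always
reported in Pa. Every result object records the area model and length
source that produced it, and pipeline outputs embed the fully resolved run
configuration.

## Synthetic specimens

The generator is the package's ground truth. A speckle pattern is rendered
as anti-aliased dark dots (intensity 25) on a light background (230) with a
mild Gaussian blur (σ = 0.8 px) standing in for optical defocus; the blur
keeps intensity gradients smooth enough for sub-pixel correlation.
Defaults — 0.02 dots/px², radii 2–4 px on a 256×512 px raster at
0.05 mm/px — give a dense, non-repeating texture comparable to a
spray-painted face filmed at desk scale.

Deformation is prescribed, not simulated: axial stretch λ(t) ≥ 1 about the
image centre, transverse stretch λ(t)^(−ν(t)). The exponent form is the
true-strain-consistent contraction: it makes
ν = −ε_transverse/ε_axial hold exactly with logarithmic strains, so the
generator and the Poisson estimator share one definition. ν(t) schedules
are piecewise-linear in axial true strain between stated endpoints — the
experimental literature reports endpoints, not functional forms. An
optional crack is a single straight line transverse to loading; the
material below it translates rigidly by the opening displacement, which is
zero before onset and non-decreasing after. Frames are resampled through
the inverse warp with cubic splines; pixels inside an open crack have no
material pre-image and are filled dark. Photometric corruption is additive
Gaussian intensity noise, clipped to [0, 255]. The frame at t = 0 is always
the undeformed reference.

Matching force traces are built in true-stress space: exactly linear at the
prescribed modulus up to a knee, then a monotone concave hand-off whose end
slope makes the force maximum land exactly on the constructed fracture
sample (so `max(force) = peak_force` holds sample-exactly and parameter
recovery is well-posed). Post-peak, the isotropic archetype drops to 2 % of
peak within two samples (brittle, homogeneous matrix); the anisotropic
archetype descends in ≥ 2 stages — rapid partial drop, partial recovery —
emulating microcrack bridging delayed by a dispersed phase, with a short
decaying tail so every stage peak is a proper local maximum. The crosshead
column is the schedule-implied travel h₀(λ−1); optional grip slippage adds
machine travel the specimen never sees, and an optional clock offset
emulates camera-trigger lag. The default texture-analyser sampling rate is
500 Hz (exposed as a parameter; instruments vary), video default 25 fps.

What the generator does **not** emulate: out-of-plane motion, lighting
drift, lens distortion, heterogeneous material response (other than the
single idealized crack), or physically based constitutive behaviour.
Passing tests therefore demonstrate correctness of the measurement chain,
not robustness to every artefact of a real laboratory video.

## Subset correlation

A regular lattice of odd-sized subsets (default 21 px side, 12 px step) is
laid over the region of interest; subsets that would overhang the image
with their search margin are excluded. Every frame is matched against the
fixed reference (frame 0) — not incrementally — so errors do not
accumulate; each subset's integer search is seeded with its displacement in
the previous frame, which keeps the exhaustive zero-normalized
cross-correlation (ZNCC) search radius down to the inter-frame increment
(default ±5 px). ZNCC is invariant to affine intensity changes, so
photometric offset/gain drift does not bias the match.

Sub-pixel refinement has three levels, in increasing fidelity:

- `quadratic`: closed-form peak of a quadratic fit to the 3×3 ZNCC
  neighbourhood (no iteration; ~0.02 px accuracy on good speckle);
- `gradient`: translation-only Gauss–Newton on brightness constancy;
- `affine` (default): a first-order subset shape function — each subset may
  translate and deform affinely. Translation-only matching is biased once
  the strain across a subset reaches a few tenths of a pixel (at λ = 1.1 a
  21 px subset stretches by ~1 px and the per-subset error reaches
  ~0.13 px RMS); with the affine warp the same scene tracks at ~0.001 px
  RMS. The affine parameters are warm-started from the previous frame and
  discarded after refinement; strain is always computed from the subset
  field, never from per-subset warp parameters.

Cubic-spline interpolation coefficients are computed once per frame and
shared by all subsets. A subset whose ZNCC falls below the validity
threshold (default 0.8) is flagged invalid from that frame onward — with
the affine model, correctly tracked subsets stay above ~0.95 even at 0.25
strain under noise, while subsets straddling an open crack linger around
0.65–0.78 with meaningless displacements, so 0.8 separates the two cleanly.
Flat (zero-variance) subsets are marked degenerate rather than aborting the
run; a frame in which every subset is lost raises a tracking-lost signal
naming the frame.

Strain at a subset is obtained from a least-squares plane fit of (u, v)
over the valid subsets within a window (default radius 2 lattice steps);
the fitted displacement gradient gives F = I + ∇u and the logarithmic
(Hencky) strain 0.5·ln(FᵀF) via eigendecomposition. Subsets with fewer than
three non-collinear valid neighbours are flagged. Rendered strain maps use
fixed colour bounds (0.01–0.45) so frames and specimens are comparable.

## Virtual extensometry and the dynamic Poisson's ratio

Three extensometers are placed per specimen: gauge (spanning h₀ along the
loading axis), crack zone (default 3 mm, centred on the configured or
detected crack line), and transverse (spanning the initial width at
mid-gauge). Each anchor is a set of three points symmetric about the anchor
along the perpendicular axis, so averaging cannot bias the measured
component. Anchor displacement is interpolated bilinearly on the regular
subset lattice — exact for locally linear displacement fields, which is
what makes the closed-form checks (λ = 1.2 on h₀ = 8.5 mm → 10.2 mm) pass
to 0.02 mm — falling back to inverse-distance weighting over valid subsets
within 1.5 lattice steps when a cell corner is invalid (e.g. near the
crack). Frames where no valid subset is near an anchor carry a gap (NaN)
rather than an extrapolated value.

The dynamic Poisson's ratio uses true strains in both axes,
ν(t) = −ln(w/w₀)/ln(h/h₀). Below an axial-strain floor (default 0.005) the
ratio is a 0/0 and is omitted; values outside a sanity band (−0.1 … 0.6)
are kept but flagged. By default ν is computed over the whole gauge length
and width, crack area included — so past fracture the axial strain contains
both material elongation and crack opening while the transverse strain
contains only elongation. A crack-corrected ν is deliberately not invented;
users who want the material-only ratio can pass the crack extensometer's
span explicitly.

Synchronization interpolates force and machine distance linearly onto the
frame clock after applying a constant, user-supplied trigger offset
(default 0). No automatic cross-correlation alignment is attempted — an
explicit offset is auditable, a fitted one is not.

## Stress–strain curves and tensile parameters

Curves are built for every available combination of length source
(machine travel, DIC gauge, DIC crack zone) and area model:

- constant-volume: A(t) = h₀/h(t) · A₀ (exact for ν = 0.5);
- dynamic-Poisson: A(t) = w_DIC(t) · (w_DIC(t)/w₀) · t₀, assuming the
  unobserved thickness shrinks by the same fraction as the measured width.

When the width follows the incompressible contraction w₀·(h₀/h)^½ the two
models agree to 1e-10 relative error (closed-form identity); for ν < 0.5
the dynamic-Poisson area is larger and its stress correspondingly lower.

The fracture point is the last stress maximum before the first window
(default 2 % of the curve, minimum 3 samples) over which stress falls by at
least 30 % of the running peak; "sharp decrease" has no standard
quantification, so both knobs are configuration keys. The Young's modulus
is the slope of the best-R² contiguous window of span ≥ 0.02 strain
(earliest window wins ties); if no window reaches R² = 0.99 the best one is
still reported with a below-floor flag rather than silently degrading.
Toughness is the trapezoidal area under the curve, reported both to the
fracture point and over the full recorded curve: under displacement control
a brittle specimen's crack outruns the crosshead and the to-fracture
integral overestimates the work of fracture, so both labelled variants are
emitted and the choice is left to the analyst. Anisotropy indices divide
per-direction means (parallel over perpendicular) of fracture stress,
modulus and toughness.

The gap-proportional deformation-rate helper keeps the nominal engineering
strain rate constant across mould sizes: rate = reference_rate/reference_gap
× gap (defaults 60.0 mm/min over 26.0 mm).

## Validation problem sizes and numerical choices

The standing validation scenario (`tensiledic.studies`) renders 201 frames
at 256×512 px / 0.05 mm/px (8 s at 25 fps, axial true strain ramping to
0.25) and tracks a ~17×19 subset grid — about 320 points — through the full
pipeline; the anisotropic schedule runs ν from 0.43 to 0.11 and the
isotropic one from 0.18 to 0.05, and the recovered endpoints land within
±0.01 of the prescribed values on noiseless imagery. Unit tests use smaller
rasters (≤ 256 px) and ≤ 30 frames so the whole suite stays in the
minutes range on one CPU.

Numerical details worth knowing: sub-pixel solvers stop at 1e-4 px
parameter updates or 10 iterations; the integer ZNCC search carries one
extra ring so the 3×3 quadratic fit exists at the nominal search boundary;
modulus window scans use prefix-sum regression statistics (O(1) per
window); degenerate windows (zero strain variance) are skipped; curve
samples with non-positive or missing lengths propagate as NaN stress and
are ignored by the extractors. Seeded `numpy.random.Generator` instances
make every generator bit-reproducible; tracking a sequence forward or
reversed against the same reference agrees to the solver tolerance (the
search seed is the only order-dependent quantity).

## Known limitations

- Single-camera, in-plane analysis: out-of-plane motion contaminates both
  strains; the dynamic-Poisson area model infers thickness from width.
- The affine shape function is first-order; strongly curved displacement
  fields within one subset (tight crack-tip fields) are beyond it, and such
  subsets are expected to decorrelate and drop out instead.
- Crack handling assumes one straight transverse crack; no crack-path
  tracing. The provided helper locates the crack line only as the argmax of
  the axial-strain band.
- Means and SDs across replicate specimens are reported without hypothesis
  testing; rate dependence and viscoelasticity are emulated by the
  generator's schedules, not modelled.
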