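# Methods

This note documents the models behind `spherodrop`, the assumptions they
make, the defaults they ship with, and what the synthetic-data tests do
and do not demonstrate.

## Scope and setting

The package models the quantitative steps of an automated hanging-drop
spheroid workflow: a non-contact dispenser builds microliter hanging
drops out of calibrated nanoliter droplets on an inverted plate lid;
cells settle to the drop apex and form a spheroid over days; a standard
swing-bucket centrifuge then detaches the drops and transfers each
spheroid into the well (or hydrogel-loaded well) directly beneath it.
Everything wet-lab — culturing, viability, hydrogel behavior — is out of
scope; the package computes the physics, plans the dispensing, measures
the images, and simulates the transfer.

## Sessile-drop geometry

A hanging drop on a flat substrate is modeled as a spherical cap. The
cap is closed by two numbers, volume `V` and contact angle `θ`:

    V = (π/3)·R_s³·(2 − 3cosθ + cos³θ),    r = R_s·sinθ

with `R_s` the generating-sphere radius and `r` the contact-line radius.
The bracketed polynomial is strictly positive on (0°, 180°), so
inversion for `R_s` is a closed-form cube root. Gravity-induced shape
distortion is neglected: at 1–4 µL the capillary length of aqueous
medium (~2.4 mm) exceeds the drop dimensions, so the spherical-cap
approximation is standard. Contact-angle hysteresis is not modeled;
measured angles enter as plain numeric inputs.

## Mixing shear stress

Reservoir mixing pushes the suspension through a tube of radius `R` at
flow `Q`; the wall shear estimate used for cell-safety screening is

    τ = μ·Q / (π·R³)

with `R` the tube **radius** (2 mm for the 4 mm inner-diameter tube used
as default). The classical Poiseuille wall-shear result carries an extra
factor of 4 (`τ_w = 4μQ/πR³`); both variants are exposed through
`wall_shear_stress(..., formula="paper" | "poiseuille")`, defaulting to
the simple estimate. Under either reading the result (71.6 or 286 mPa
at μ = 0.9 mPa·s, Q = 2 mL/s) sits far below the ~750 mPa regime where
effects on adherent mammalian cells are expected, so the safety
conclusion is insensitive to the choice. `shear_safety_check` applies a
strict `<` comparison against the critical value.

## Centrifugal detachment

Detachment is a static force balance: the centrifugal body force must
exceed the surface-tension retention force along the contact line,

    ρ·a_C·V ≥ 2π·r·γ·sinθ   ⇒   a_C ≥ 2π·r·γ·sinθ / m,  m = ρV.

Dynamic shape change during spin-up is acknowledged but not modeled; the
static balance is the planning estimate. Because `θ` on untreated
substrates is variable, `worst_case_detach_acceleration` maximizes the
threshold over all cap geometries at fixed volume (0.1° grid over
(0°, 180°); the objective `r(θ)sinθ` is smooth and single-peaked, so the
grid is more than sufficient). The worst case for aqueous medium sits
near θ ≈ 65°: ≈ 32 g for 1 µL, ≈ 15.5 g for 3 µL, scaling as V^(−2/3).
A centrifuge setting above the worst case guarantees detachment
regardless of the actual contact angle.

Defaults: density ρ = 1000 kg/m³; surface tension γ = 0.058 N/m, a
typical value for serum-supplemented culture medium (protein adsorption
pulls it well below pure water's 0.072 N/m) chosen deliberately on the
conservative side and overridable everywhere; viscosity μ = 0.9 mPa·s
(water at room temperature). Standard gravity is fixed at 9.80665 m/s².
Interfaces take µL and degrees; internals are SI.

## Transfer ballistics

Once detached, a drop is a point mass in the rotating frame subject to
the position-dependent centrifugal acceleration `Ω²·ρ⃗` (directed
outward from the spin axis) and the Coriolis acceleration `−2Ω⃗×v⃗`,
starting from rest (no detachment recoil). Gravity and air drag are
neglected — at ≥ 25 g and sub-millimeter flight distances both are
second-order. The swing bucket is idealized as fully swung out: the
plate surface is the plane `x = rotor_radius` with its normal radial;
the rotor radius is not a property of the plate and defaults to 0.15 m
(typical benchtop swing-bucket); headline results are verified
insensitive over 0.10–0.25 m.

Trajectories are integrated with fixed-step classical RK4 (default 400
steps across the gap, ≥ 200 recommended; config-exposed) until the drop
crosses the receiver plane at gap `h`; the crossing time inside the
final step is refined by bisection to machine precision, which makes the
frozen-field test case exact rather than step-limited. The landing
offset is the in-plane displacement between launch point and crossing
point; the deflection angle is `α = arctan(offset/h)`.

Two closed forms anchor the simulator. With the acceleration frozen at
its launch-site value (`position_dependent=False`) the path is a straight
line and the offset is exactly `h·tanφ` with `tanφ = u/R` the geometric
angle of a site at tangential offset `u`. With everything enabled, the
small-rotation-angle expansion of the exact solution (a straight line in
the inertial frame, rotated into the rotor frame) gives

    Δy ≈ u·h/R − (2h)^{3/2} / (3√R),

i.e. a geometric spreading term plus a Coriolis shift toward the
trailing side. Notably the Coriolis shift is independent of spin speed —
the crossing time scales as 1/Ω while the Coriolis acceleration scales
as Ω·v — so it cannot be reduced by spinning slower; it vanishes only as
the gap shrinks (∝ h^{3/2} against the geometric term's h). Both
closed forms are asserted against the integrator in the tests. The two
terms add at the trailing (rear) end of the plate and partially cancel
at the leading end, which is why rear drops deflect most and
`rear_row_advisory` flags rear columns first.

Capture accounting is evaluated at the well-opening plane (default gap
0.8 mm, well-opening radius 1.55 mm for a 384-well plate): a drop is
captured when its offset is strictly below the opening radius. In-well
motion after crossing, drop breakup, and hydrogel mechanics are not
modeled. At 25 g the maximum offset across a full 384 array is ≈
0.34 mm — comfortably inside every opening — while the same simulation
at the 11.8 mm measurement gap produces multi-millimeter deflections,
reproducing why an unstructured receiver was needed at that distance.

## Dispense planning

The dose count is `n = round_half_up(V_HD / V_D′)`, where `V_D′` is the
calibrated nanodroplet volume rescaled by a fill-level factor. Rounding
to nearest (half-up) was chosen because it minimizes the absolute
per-drop volume error; targets below half a droplet volume are rejected
as under-resolution. The fill-level correction is a monotone
piecewise-linear interpolation over a user-supplied calibration table,
clamped at the table ends — the simplest shape that inverts a slow
monotone drift without inventing curvature the calibration cannot
support. Plate layouts follow the SBS standard (96: 8×12 at 9.0 mm;
384: 16×24 at 4.5 mm), A1 origin, row-major order with an optional
serpentine flag (off by default). Mixing feasibility requires the cycle
period `1/f` to cover the round trip `2·(fraction·reservoir)/Q`.

## Image analysis

**Droplet volumetry.** Strobe images are background-subtracted
(absolute difference), thresholded (Otsu by default, fixed threshold
optional), hole-filled, and labeled; the largest component above
`min_area_px` is the droplet and the rest are satellites, which are
measured but excluded from the main volume. The volume integrates the
mask as a stack of one-pixel-high cylinders whose diameters are the row
pixel counts — exactly `Σ π(w_i/2)²` in pixel units — which assumes
rotational symmetry about the vertical flight axis. Row pixel counts
(not extremal spans) define the diameter; for concave contours the two
definitions differ and the pixel-count choice keeps volume monotone
under mask inclusion. No sub-pixel refinement is performed; the error
budget assumes integer-pixel masks, giving ≲ 3% error for ~230 µm
droplets at 10 µm/px and decreasing with pixel size.

**Spheroid morphometry.** Brightfield spheroids are dark on a bright
field: the darker Otsu class is foreground, holes are filled, and the
largest component is measured. Since Otsu always yields a split, a
contrast gate requires the two intensity classes to separate by at
least `min_class_separation` (default 4) times the larger within-class
spread — pure Gaussian noise splits at a ratio near 2.7, genuine
object/background contrast is far higher. An object counts as a
spheroid only if its equivalent diameter `d = 2√(A/π)` is at least
`min_diameter_um` (default 50 µm) and its solidity at least
`min_solidity` (default 0.85); loose aggregates fail the solidity gate.
These thresholds operationalize "successfully formed spheroid" and are
config-exposed. Size consistency uses the sample standard deviation
(n−1) in `CV = 100·sd/mean` over detected wells only.

**Group comparison.** Both groups are tested with D'Agostino–Pearson
normality (needs n ≥ 8); if both pass at α = 0.05 a two-sided t-test is
used, otherwise a two-sided Mann–Whitney U. Labels: p ≥ 0.05 "n.s.",
p < 0.05 "*", p < 0.001 "**", p < 0.0001 "***". No multiple-testing
correction is applied; comparisons are pairwise.

## Synthetic data

All generators are pure functions of (spec, seed) and bit-reproducible.
Droplet images are projected-sphere silhouettes (free-flying nanoliter
droplets are near-spherical) rendered with analytic antialiasing, plus a
clean background and optional Gaussian noise and satellites. Spheroid
plates draw true diameters from Normal(mean, cv·mean/100) truncated at
±3 sd — box-plot-shaped data without heavy tails; the family is
config-exposed in the sense that the truth table always records the
drawn values. Blank wells emulate failed drops, scattered-blob wells
emulate loose aggregates. Dispense logs apply a linear fill-level decay
to the droplet volume with optional seeded jitter and come paired with
the calibration table that inverts the drift.

What the renderers deliberately omit: optical point-spread, uneven
illumination, debris, overlapping objects, partial-well cropping, drop
oscillation shapes. Passing the recovery tests therefore demonstrates
that the measurement chain is unbiased on clean geometry at realistic
scales (diameters 80–230 µm, droplets 40–100 nL, CV ≈ 7.4%), not that
it is robust to arbitrary real microscopy artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run full-resolution physics
(closed forms and 0.1° grids are instantaneous) and full 384-site
transfer simulations at 200 RK4 steps per trajectory; recovery tests
use 60-well synthetic plates per condition, which is enough to pin the
mean within 3% and the CV within a fraction of a point of the rendered
sample's truth. Degenerate inputs fail loudly and early: non-positive
physical quantities, angles outside (0°, 180°), images without a
droplet, fewer than two detected spheroids, zero targets. Boundary
conventions worth knowing: the shear safety and well-capture
comparisons are strict (`<`), the 1.5 µL guard-band threshold is
inclusive, and dose rounding is half-up.

## Known limitations

- The detachment criterion is quasi-static; drops that deform strongly
  during spin-up may detach below the static threshold (conservative
  direction for planning).
- The simulator scores capture at the well-opening plane only; wall
  sticking inside a well — the practical reason to leave rear wells
  unseeded — is represented only through the near-wall advisory margin.
- Segmentation parameters were chosen for the synthetic renderers and
  clean brightfield data; low-contrast or debris-laden images need the
  exposed thresholds retuned.
- The fill-level correction is piecewise linear; strongly nonlinear
  dispenser drift would need a denser calibration table.
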