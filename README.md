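# spherodrop

A toolkit for the quantitative side of automated hanging-drop spheroid
workflows: planning nanoliter dispensing onto SBS microplate arrays,
estimating dispensed droplet volumes from strobe images, checking the
biophysics of reservoir mixing and centrifugal drop release, simulating
the centrifugal transfer of spheroids into receiver wells, and measuring
the resulting spheroids.

It is written for the people who run such platforms — lab automation
engineers and 3D-cell-culture researchers — who need the numbers behind
the hardware: how many doses build a 2 µL drop, whether mixing shear
will harm the cells, what centrifuge setting detaches every drop, where
each drop will land, and how consistent the resulting spheroids are.

## The models at the core

**Drop geometry and detachment.** A hanging drop is a spherical cap
linking volume, contact angle and contact-line radius:
`V = (π/3)R_s³(2 − 3cosθ + cos³θ)`, `r = R_s sinθ`. It detaches in the
centrifuge when the body force beats the surface-tension retention
force, `ρ a_C V ≥ 2πrγ sinθ`, so the required acceleration is
`a_C = 2πrγ sinθ/m`. Maximizing over all contact angles at fixed volume
gives a planning bound that works whatever the actual wetting: ≈ 32 g
for 1 µL of aqueous medium, falling as `V^(−2/3)`.

**Mixing shear.** The suspension-mixing wall shear is estimated as
`τ = μQ/(πR³)` with `R` the tube radius and screened against the
≈ 750 mPa regime critical for adherent mammalian cells.

**Transfer ballistics.** A detached drop is integrated in the rotating
frame under the position-dependent centrifugal acceleration `Ω²ρ⃗` and
the Coriolis acceleration `−2Ω⃗×v⃗` (fixed-step RK4) until it crosses
the receiver plane; the in-plane landing offset decides whether it
enters the 1.55 mm well opening beneath it. To leading order the offset
is `u·h/R − (2h)^{3/2}/(3√R)`: geometric spreading plus a spin-speed
independent Coriolis shift toward the trailing edge.

**Image analysis.** Droplet volumes come from background-subtracted,
segmented strobe images integrated as per-row cylinder stacks
(`V = Σ π(w_i/2)²·s³`). Spheroids are segmented from brightfield
micrographs, gated by equivalent diameter `d = 2√(A/π)` and solidity,
and summarized as mean / sd / CV plus drop- and spheroid-generation
efficiencies.

A synthetic-fixtures module renders droplet and spheroid images with
known ground truth so the whole chain is testable without any external
data. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Check the mixing shear and the centrifuge settings for 1 µL and 3 µL
drops:

```
$ spherodrop physics --shear --detach-ul 1
wall shear stress: 71.6 mPa (critical 750 mPa) -> PASS, margin 10.5x
worst-case detachment for 1.0 µL: 32.3 g at contact angle 65.5 deg

$ spherodrop physics --detach-ul 3
worst-case detachment for 3.0 µL: 15.5 g at contact angle 65.5 deg
```

Mixing at the maximum 2 mL/s through the 4 mm tube stays an order of
magnitude below the critical shear, and any 1 µL drop — whatever its
contact angle — releases below 33 g; 3 µL drops need under 16 g, so a
25 g spin detaches them with margin.

Plan three 384-format plates of 2 µL drops built from 50 nL droplets at
3.2×10⁴ cells/mL:

```
$ spherodrop plan --format 384 --plates 3 --drop-ul 2 --droplet-nl 50 \
      --conc-per-ml 3.2e4 --out map.csv
1152 positions x 40 doses (46080 total), 64 cells/drop -> map.csv
```

Each of the 1152 positions receives 40 nanodroplet doses and an
expected 64 cells. Then simulate the harvest spin at 25 g:

```
$ spherodrop harvest-sim --rcf 25 --rotor-m 0.15 --gap-mm 0.8 --format 384
capture 100.0%, max deflection 0.340 mm -> harvest.csv
```

The worst-placed drop (trailing edge of the plate, where geometric
spreading and the Coriolis shift add) lands 0.34 mm from its source —
well inside the 1.55 mm well opening, so every spheroid is captured.

The same operations are available as library functions
(`spherodrop.worst_case_detach_acceleration`,
`spherodrop.generate_array`, `spherodrop.capture_report`, ...) for use
in notebooks and pipelines.

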