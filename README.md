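# cspine10

A reduced-order model of the 10-year-old child cervical spine for tensile
failure and sagittal bending analysis, written for pediatric injury
biomechanics work (vehicle-safety research, restraint and airbag design
studies) where child-specific soft-tissue failure properties have to be
inferred from adult data.

Pediatric cadaveric material data are essentially nonexistent, so child
models are built by scaling adult properties and then calibrating the few
free failure parameters against the handful of published pediatric segment
tests.  This package implements that whole chain as a tested library plus
CLI:

1. **Scaling** — adult disc failure forces map to the child as
   `F′ = F_adult · α′ · G_S²` with the disc material scale `α′ = 0.782` and
   the squared geometric scale `G_S² = 0.723²`; dividing by the child
   annulus cross-section gives candidate disc failure stresses.  Adult
   flexion/extension corridors scale by the moment ratio `R_M = λ_x³ ≈ 0.38`
   and the angle ratio `R_θ = λ_z/λ_x ≈ 1.1`.
2. **Constitutive curves** — each ligament is a tension-only bar with a
   sigmoidal force–deflection curve through a toe point A, a linear-region
   point B and a tolerance point C.  Child control points follow
   `d_i = ε_max (ε_i/ε_max) l` and
   `f_i = F_max (F_i/F_max) α_i G_S² / N_i`, keeping the adult curve shape
   while shrinking failure force and deflection.  Bone follows power-law
   plasticity (`σ = Eε` below yield, `σ = kε^N` above); the annulus ground
   substance is a compressible Hill foam evaluated in uniaxial stress.
3. **Solver** — segments are parallel networks of ligament bars, disc
   sub-elements (deleted when tensile stress reaches a critical value) and
   compression-only facet gap elements, loaded quasi-statically by
   prescribed displacement or rotation with progressive element deletion.
   The force–displacement history yields the ultimate point and a 10–90 %
   least-squares stiffness; segments chain in series for whole-spine
   tension.
4. **DOCE calibration** — a full factorial over four ligament
   failure-strain increases (baseline, +25, +50, +75 %) and seven disc
   failure stresses (15–45 MPa) per disc-bearing segment (strain-only for
   the occiput–C2 complex, 60 runs in total), with ANOVA-style effect
   ranking and two-stage nearest-target parameter selection (stress by
   ultimate force, then strain by ultimate displacement).

## Worked example

```python
from cspine10 import (build_segment_geometry, assemble_segment,
                      simulate_tension)

geom = build_segment_geometry("C4-C5")
asm = assemble_segment(geom, disc_failure_stress=30.0, strain_increase_pct=50.0)
res = simulate_tension(asm, geom.max_displacement, step=0.01)
print(f"ultimate {res.ultimate_force:.1f} N at {res.ultimate_displacement:.2f} mm")
for ev in res.failure_events:
    print(f"  {ev.displacement:5.2f} mm  {ev.element}  ({ev.kind})")
```

prints

```
ultimate 426.8 N at 4.65 mm
   0.80 mm  disc_layer_1  (disc)
   1.00 mm  disc_layer_2  (disc)
   1.27 mm  disc_layer_3  (disc)
   2.71 mm  PLL@C2-C5  (ligament_bar)
   4.65 mm  ALL@C2-C5  (ligament_bar)
```

i.e. with the calibrated parameters (+50 % ligament strain, 30 MPa disc
failure stress) the C4–C5 fixture fails the way the pediatric segment is
expected to: the disc periphery tears first (partial disc failure), the
posterior longitudinal ligament follows, and the ultimate force coincides
with anterior longitudinal ligament failure.  The same commands are
available from the shell:

```bash
cspine10 simulate --mode tension --level C4-C5 --failure-stress 30 \
    --strain-increase 50 --out run.csv
cspine10 doce run --out doce.csv && cspine10 doce analyze --table doce.csv --out doce.json
cspine10 scale-corridor --in adult_corridor.csv --out child_corridor.csv
```

## Layout

- `src/cspine10/scaling.py` — scale-factor set, disc failure scaling, corridor ratios
- `src/cspine10/constitutive.py` — ligament curves, power-law bone, Hill foam, disc element law
- `src/cspine10/geometry.py` — parametric sagittal segment fixtures and assembly
- `src/cspine10/solver.py` — quasi-static tension/bending with element deletion
- `src/cspine10/doce.py` — factorial design, batch runs, effects, calibration
- `src/cspine10/library.py`, `data/*.yaml` — packaged material/ligament tables
- `src/cspine10/config.py`, `io.py`, `cli.py` — configuration, CSV I/O, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
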