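# Methods

## Scope and model class

The package is a reduced-order (lumped-element) re-implementation of a
10-year-old cervical spine failure analysis: instead of a volumetric finite
element mesh it represents each functional spinal unit as a parallel
network of one-dimensional axial elements in the sagittal plane (x
anterior, z superior).  This keeps every computation closed-form-checkable
while retaining the quantities the analysis actually reasons about —
force–displacement and moment–angle histories, failure sequences, ultimate
points, 10–90 % stiffnesses, and the factorial calibration of the two free
failure parameters.  Volumetric meshing, contact, bone fracture and
muscle activation are out of scope.

## Scaling laws

Adult-to-child conversion uses six dimensionless factors (geometric
`G_S = 0.723`, directional `λ_x = 0.723`, `λ_z = 0.793`, material
`α_bone = 0.805`, `α_disc = 0.782`, `α_ligament = 0.893`).  Cross-sectional
quantities always scale with `G_S²`; the implementation never stores the
area scale separately, which makes the disc failure force
(`F′ = F_adult α′ G_S²`) and the failure stress (`F′/A_child`) mutually
consistent.  With the packaged adult forces (571, 505 and 1280 N) and
child annulus areas (14.66 and 17.74 mm²) this reproduces the four
candidate disc failure stresses 15.92, 35.70, 11.63 and 29.49 MPa to
within round-off.  Note one bookkeeping subtlety: the scaled force printed
alongside the 1280 N rows in the source literature (560.10 N) is not
consistent with its own stresses; 1280 × 0.782 × 0.723² ≈ 523.2 N is, and
that is what the package computes.  Corridor scaling multiplies angles by
`λ_z/λ_x ≈ 1.097` and moments by `λ_x³ ≈ 0.378`.

## Ligament curves

Each ligament is tension-only with a piecewise-linear curve through the
origin, toe point A, linear-region point B and tolerance point C.  The
normalized control ratios are shared per ligament family; child curves are
obtained by mapping strain ratios onto `ε_max · l` (l = child model
length, the attachment distance in the fixture) and scaling forces by
`α_ligament G_S² / N_i` for `N_i` parallel bars.  A piecewise-linear
interpolant was chosen deliberately: the three points are the only
published information about the sigmoid, and a polyline through them is
the minimal, exactly testable reading.  Upper-cervical (occiput–C2)
ligaments have published failure forces and deflections rather than
strains; their strains are derived from the implied adult lengths
(`l_adult = d_max/ε_max`), and each row borrows the normalized control
points of a named surrogate family.

The strain-increase calibration parameter stretches the deflection axis by
`1 + pct/100` with forces unchanged, so curve shape and failure force are
retained.  Child model lengths in the default fixtures are kept at or
below two-thirds of the (implied) adult lengths; this encodes the
requirement that even at +50 % strain no child failure deflection exceeds
the corresponding adult one (a geometric scale of 0.723 alone would
violate it, since 0.723 × 1.5 > 1).

## Point material laws

Bone (cortical, cancellous, endplate) uses isotropic power-law plasticity:
`σ = Eε` below the yield strain `ε_y = (k/E)^{1/(1−N)}` and `σ = kε^N`
above, continuous at yield by construction (cortical: E = 13 440 MPa,
k = 355 MPa, N = 0.277, ε_y ≈ 0.0066).  These laws are provided for
completeness and for the disc fiber plateau; a 3-D return-mapping
plasticity is not needed at this model order.

The annulus ground substance is a Hill (Storakers-type) compressible foam
with `n = 2`, `C = (0.090, 1.643, −0.699) MPa`, `b = (4, −1, −2)`:

    W = Σ_j C_j/b_j [λ1^{b_j} + λ2^{b_j} + λ3^{b_j} − 3 + (J^{−n b_j} − 1)/n]

Uniaxial nominal stress assumes homogeneous stress with free lateral
faces; the common lateral stretch solves the zero-lateral-stress condition
by bracketed root finding (residual ≲ 1e−10 MPa), and the axial stress is
the energy derivative along that relaxed path.  Because the exact energy
convention of production FE codes is not published, correctness is defined
internally by an energy-derivative oracle: the returned stress matches a
central finite difference of the relaxed strain-energy density to better
than 0.1 % everywhere tested.  The disc element caches the uniaxial curve
on a dense stretch grid (4096 points on [0.05, 6]); interpolation error is
below 1e−4 MPa.

## Disc element and the synthetic fixtures

The disc (growth plate / endplate cartilage failure site) is an axial
element split into four independently failing sub-elements, each with
composite stress `σ(ε) = (1−φ) t_hill(1+ε) + φ σ_fiber(ε)` (fiber volume
fraction φ = 0.2) and a tensile deletion threshold equal to the
calibrated failure stress.  Compression loads only the ground substance
and never triggers deletion.

The default geometry is a synthetic stand-in for subject-specific
segmented anatomy — attachment coordinates are order-of-magnitude
anatomical plumbing, fully exposed in `data/segments.yaml`, and make no
subject-specific claim.  Ligament bars are vertical so the attachment
distance equals the constitutive model length and tensile elongation
equals the imposed displacement exactly.  The disc sub-elements emulate
the radial build-up of the annulus: three thin, stiff outer lamellae
(linear fiber moduli 750/600/475 MPa, areas ≲ 1 mm²) that reach the
failure stress early, and one large inner bulk (≈ 12–14 mm²) whose fibers
follow a saturating power-law (E = 700 MPa, k = 130 MPa, N = 0.05),
emulating fiber-reorientation plateau behaviour.  These layer parameters
were designed in closed form so that, at the calibrated parameters, the
fixtures reproduce the failure narratives the model class is supposed to
show: peripheral (partial) disc failure first, then PLL, with the ultimate
force at ALL failure on C4–C5; disc then PLL (ultimate at PLL) on C6–C7;
tectorial membrane first with the ultimate at joint-capsule failure on
the occiput–C2 complex.  Because the inner disc bulk saturates below
30 MPa within the simulated displacement range, the ultimate point is
ligament-controlled for failure stresses of 30 MPa and above, which
produces the plateau of ultimate force/displacement from 30 to 45 MPa;
below 30 MPa the disc ruptures first and the ultimate force falls with
the threshold.

What passing tests on these fixtures do show: the solver, curve
construction and calibration logic jointly reproduce the published
qualitative failure behaviour and orderings.  What they do not show:
agreement with volumetric FE force levels (the parallel-bar reduction
carries roughly the summed soft-tissue capacity, hundreds of newtons
rather than the ≳ 1 kN a meshed disc transmits), subject-specific
geometry effects, rate effects, or gradual intra-ligament fiber failure.

## Solver

Loading is quasi-static displacement control (no inertia or damping; the
loading of interest is rate-independent): per step the driven boundary
translates (tension) or rotates about the configured center (bending,
disc centroid by default; the occiput–C2 complex drives its inferior
boundary).  Element deletion is evaluated once per step after the
elongation update; all failures in a step apply simultaneously, and the
failing element's force is still included in that step's reaction, so the
recorded drop appears one step later.  Default steps are 0.01 mm and
0.05°; halving the step changes the ultimate force of the default
fixtures by well under 1 %.  Ultimate-point ties resolve to the earliest
step.  The 10–90 % stiffness is the ordinary least-squares slope over
pre-ultimate samples with force in [0.1, 0.9] × ultimate.  Bending runs
are nominally non-destructive: failures there are recorded as warning
events rather than aborting.  Facet gaps carry compression only, engage
once the configured gap closes (0.6 mm, 150 N/mm default), and dominate
the extension response, as facet contact should.

Whole-spine tension chains segments in series (common force, summed
displacements) by monotone root finding on the shared force.  Small
pre-ultimate load drops from partial failures make a segment's raw curve
non-monotone; under force control those unstable sub-branches are skipped
quasi-statically, so the chain inverts each segment's running-maximum
loading envelope, and beyond the chain peak the weakest segment (smallest
ultimate force) follows its softening branch while the others unload
along their loading curves.  Failure localizes in, and is reported for,
the weakest segment.

## Factorial calibration

The design crosses four strain increases (0/25/50/75 %) with seven failure
stresses per disc-bearing segment plus strain-only runs for the
occiput–C2 complex: 4×7×2 + 4 = 60 tension simulations.  The seven stress
levels default to 15–45 MPa in 5 MPa steps — only the range and count are
prescribed, so uniform spacing is the minimal reading and the levels are
configurable.  Effects are ranked by a classical balanced two-way
decomposition (main-effect and interaction sums of squares from cell and
marginal means; total SS decomposes exactly).  With one observation per
cell the residual has zero degrees of freedom, so main-effect F statistics
use the interaction mean square as the error term (the standard
unreplicated-factorial practice) and the interaction's own F is undefined;
Pareto ranking therefore uses the effect sums of squares, which is
well-defined in both the replicated and unreplicated cases.  Parameter
selection is two-stage, following the calibration narrative: the stress
level whose strain-averaged ultimate force is nearest the target force,
then the strain level whose ultimate displacement at that stress is
nearest the target displacement; ties resolve to the lower level.  The
packaged targets (14.4/5.0/6.4 mm and 2.185/1.277/1.623 kN for C0–C2,
C4–C5, C6–C7) are stored constants interpolated from 9- and 12-year-old
tests; their derivation from raw cadaveric data is out of scope.

## Numerical and design choices

- Units package-wide: N, mm, MPa, N·m, degrees; conversion only at I/O.
- Scale factors are validated to (0, 1]; the identity set is available for
  adult sanity checks.
- The Hill-foam lateral solve brackets the root in [1e−3, 50] with
  near-machine tolerance; the disc element interpolates the cached curve.
- Geometry is deterministic; optional robustness jitter perturbs
  attachment x-coordinates through an explicit seed, and the facet tracks
  the jittered capsular ligament so the facet/CL co-location invariant is
  preserved.
- CSVs are comma-separated, '.'-decimal, UTF-8, LF, full float precision,
  and re-read with round-trip float parsing; every CLI run logs config
  hash, package version and seed.
- Simulated problem sizes (≈ 500–1600 steps per segment run, 60-run
  factorial) were chosen so the whole calibration remains interactive on
  one core while step-halving checks stay below 1 % drift.

## Known limitations

- Absolute force levels are those of a parallel bar network, not of a
  volumetric disc; comparisons with experiments are qualitative
  (sequences, orderings, trends), which is also what the tests assert.
- No viscoelasticity, laxity beyond the toe region, or gradual
  intra-ligament failure; a bar is either intact or deleted.
- The sagittal-plane reduction merges paired out-of-plane structures
  (capsular ligaments, alar ligaments) into doubled element counts and
  cannot represent lateral bending or axial rotation.
- Bending validation is qualitative: moments are resisting-moment sums of
  bar tensions and facet contact about a configured center; no corridor
  fitting is attempted.
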