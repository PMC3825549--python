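# Default parametric sagittal-plane segment fixtures.
#
# Coordinates: x anterior (+), z superior (+), in mm, in the segment's local
# frame.  Ligament bars are vertical, centred on the joint mid-plane, so
# the Euclidean attachment distance equals the child model length used in
# the curve construction (single source of truth).  Attachment coordinates
# are order-of-magnitude anatomical plumbing, not subject-specific claims;
# the disc layer areas/stiffnesses emulate the radial annulus build-up
# (thin stiff outer lamellae, compliant inner bulk) so that tensile failure
# progresses from the periphery inward.
#
# Disc fiber laws: linear -> {kind, e_modulus}; power_law -> {kind,
# e_modulus, k, n_hard} (saturating, emulating fiber-reorientation
# plateau).  fiber_fraction is the lamella volume fraction of the annulus.
C4-C5:
  driven_boundary: superior
  rotation_center: [0.0, 2.0]
  max_displacement_mm: 5.0
  max_angle_deg: 10.0
  disc:
    area_mm2: 14.66
    height_mm: 4.0
    fiber_fraction: 0.2
    layers:
      - {area_mm2: 0.50, x: 1.6, fiber_law: {kind: linear, e_modulus: 750.0}}
      - {area_mm2: 0.80, x: -1.6, fiber_law: {kind: linear, e_modulus: 600.0}}
      - {area_mm2: 1.00, x: 0.8, fiber_law: {kind: linear, e_modulus: 475.0}}
      - {area_mm2: 12.36, x: 0.0, fiber_law: {kind: power_law, e_modulus: 700.0, k: 130.0, n_hard: 0.05}}
  facet: {x: -14.0, gap_mm: 0.6, stiffness_n_per_mm: 150.0}
  ligaments:
    - {type: ALL, library_level: C2-C5, x: 8.0, length_mm: 10.0, n_elements: 1}
    - {type: PLL, library_level: C2-C5, x: -6.0, length_mm: 10.0, n_elements: 1}
    - {type: CL, library_level: C2-C5, x: -14.0, length_mm: 6.0, n_elements: 2}
    - {type: LF, library_level: C2-C5, x: -22.0, length_mm: 8.0, n_elements: 1}
    - {type: ISL, library_level: C2-C5, x: -30.0, length_mm: 12.0, n_elements: 1}

C6-C7:
  driven_boundary: superior
  rotation_center: [0.0, 2.1]
  max_displacement_mm: 5.5
  max_angle_deg: 10.0
  disc:
    area_mm2: 17.74
    height_mm: 4.2
    fiber_fraction: 0.2
    layers:
      - {area_mm2: 0.90, x: 1.7, fiber_law: {kind: linear, e_modulus: 525.0}}
      - {area_mm2: 1.20, x: -1.7, fiber_law: {kind: linear, e_modulus: 370.0}}
      - {area_mm2: 1.50, x: 0.85, fiber_law: {kind: linear, e_modulus: 285.0}}
      - {area_mm2: 14.14, x: 0.0, fiber_law: {kind: power_law, e_modulus: 700.0, k: 130.0, n_hard: 0.05}}
  facet: {x: -15.0, gap_mm: 0.6, stiffness_n_per_mm: 150.0}
  ligaments:
    - {type: ALL, library_level: C6-C7, x: 9.0, length_mm: 11.0, n_elements: 1}
    - {type: PLL, library_level: C6-C7, x: -6.0, length_mm: 9.0, n_elements: 1}
    - {type: CL, library_level: C6-C7, x: -15.0, length_mm: 6.0, n_elements: 2}
    - {type: LF, library_level: C6-C7, x: -23.0, length_mm: 8.0, n_elements: 1}
    - {type: ISL, library_level: C6-C7, x: -32.0, length_mm: 12.0, n_elements: 1}

C0-C2:
  driven_boundary: inferior
  rotation_center: [0.0, 6.0]
  max_displacement_mm: 16.0
  max_angle_deg: 12.0
  disc: null
  facet: {x: -8.0, gap_mm: 0.6, stiffness_n_per_mm: 150.0}
  ligaments:
    - {type: AA-OM, library_level: OC-C1, x: 11.0, length_mm: 11.5686, n_elements: 1}
    - {type: ALL, library_level: C1-C2, x: 8.0, length_mm: 10.7843, n_elements: 1}
    - {type: Apical, library_level: OC-C2, x: 2.0, length_mm: 11.4815, n_elements: 1}
    - {type: Alar, library_level: OC-C2, x: 0.0, length_mm: 4.2121, n_elements: 2}
    - {type: CLV, library_level: OC-C2, x: -1.0, length_mm: 5.1667, n_elements: 1}
    - {type: TM, library_level: OC-C2, x: -3.0, length_mm: 9.7561, n_elements: 1}
    - {type: JC, library_level: OC-C1, x: -8.0, length_mm: 2.4672, n_elements: 2}
    - {type: JC, library_level: C1-C2, x: -9.0, length_mm: 2.9068, n_elements: 2}
    - {type: LF, library_level: C1-C2, x: -14.0, length_mm: 4.9817, n_elements: 1}
    - {type: PA-OM, library_level: OC-C1, x: -18.0, length_mm: 3.3854, n_elements: 1}
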