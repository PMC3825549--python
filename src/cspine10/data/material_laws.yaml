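# Material laws and scale factors for the 10-year-old cervical spine model.
# Units: MPa for moduli/stresses, dimensionless elsewhere.
scale_factors:
  g_s: 0.723          # dimensional (geometric) scale factor, child/adult
  lambda_x: 0.723     # anteroposterior direction scale
  lambda_z: 0.793     # superoinferior direction scale
  alpha_bone: 0.805   # bone material scale (from child/adult QCT densities)
  alpha_disc: 0.782   # disc material scale
  alpha_ligament: 0.893  # ligament material scale

power_law_plasticity:
  cortical_bone: {e_modulus: 13440.0, k: 355.0, n_hard: 0.277, poisson: 0.3}
  cancellous_bone: {e_modulus: 241.0, k: 5.73, n_hard: 0.274, poisson: 0.3}
  endplate: {e_modulus: 4480.0, k: 118.0, n_hard: 0.277, poisson: 0.3}

elastic:
  growth_plate: {e_modulus: 25.0, poisson: 0.4}
  endplate_cartilage: {e_modulus: 23.8, poisson: 0.4}
  facet_cartilage: {e_modulus: 10.0, poisson: 0.4}

hill_foam:
  annulus_ground_substance:
    n: 2.0
    c: [0.090, 1.643, -0.699]
    b: [4.0, -1.0, -2.0]

nucleus: {bulk_modulus: 1720.0}

# Adult disc failure forces (N) and the child annulus cross-sections (mm^2)
# used to derive candidate disc failure stresses.
disc_failure:
  C4-C5:
    af_cross_section_child: 14.66
    adult_forces:
      - {force: 571.0, source: Yoganandan}
      - {force: 1280.0, source: Kasra}
  C6-C7:
    af_cross_section_child: 17.74
    adult_forces:
      - {force: 505.0, source: Yoganandan}
      - {force: 1280.0, source: Kasra}
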