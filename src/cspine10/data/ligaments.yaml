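# Ligament failure library for the child cervical spine model.
#
# control_points: normalized (strain ratio, force ratio) of the toe point A
# and linear-region end B of the sigmoidal force-deflection curve; the
# tolerance point C is (1, 1) by definition.  Ratios are shared across
# spinal levels for a given ligament family.
#
# subaxial: adult failure strain eps_max (dimensionless) and force f_max (N)
# per segment, plus the adult model ligament length (mm) used to express the
# adult failure deflection when checking child curves against it.
#
# upper_cervical: adult failure force f_max (N) and deflection d_max (mm)
# for the occiput-to-C2 complex; `law` names the surrogate ligament family
# whose normalized control points apply; eps_max is the adult failure
# strain implied by the adult model ligament length (adult_length =
# d_max / eps_max).
control_points:
  ALL: {eps1_ratio: 0.211, force1_ratio: 0.108, eps2_ratio: 0.772, force2_ratio: 0.859}
  PLL: {eps1_ratio: 0.250, force1_ratio: 0.098, eps2_ratio: 0.773, force2_ratio: 0.779}
  CL:  {eps1_ratio: 0.260, force1_ratio: 0.150, eps2_ratio: 0.760, force2_ratio: 0.880}
  LF:  {eps1_ratio: 0.286, force1_ratio: 0.209, eps2_ratio: 0.762, force2_ratio: 0.893}
  ISL: {eps1_ratio: 0.308, force1_ratio: 0.201, eps2_ratio: 0.744, force2_ratio: 0.909}

subaxial:
  C2-C5:
    ALL: {eps_max: 0.31, f_max: 93.0, adult_length: 17.0}
    PLL: {eps_max: 0.18, f_max: 71.0, adult_length: 16.0}
    CL:  {eps_max: 1.48, f_max: 120.0, adult_length: 10.0}
    LF:  {eps_max: 0.77, f_max: 121.0, adult_length: 13.0}
    ISL: {eps_max: 0.61, f_max: 39.0, adult_length: 19.0}
  C6-C7:
    ALL: {eps_max: 0.35, f_max: 145.0, adult_length: 17.0}
    PLL: {eps_max: 0.34, f_max: 188.0, adult_length: 16.0}
    CL:  {eps_max: 1.16, f_max: 181.0, adult_length: 10.0}
    LF:  {eps_max: 0.88, f_max: 129.0, adult_length: 13.0}
    ISL: {eps_max: 0.68, f_max: 39.0, adult_length: 19.0}

upper_cervical:
  - {level: OC-C1, type: JC,     f_max: 320.0, d_max: 9.9,  law: CL,  eps_max: 2.54}
  - {level: OC-C1, type: AA-OM,  f_max: 232.0, d_max: 18.9, law: ALL, eps_max: 0.68}
  - {level: OC-C1, type: PA-OM,  f_max: 83.0,  d_max: 18.1, law: LF,  eps_max: 1.28}
  - {level: C1-C2, type: ALL,    f_max: 263.0, d_max: 11.8, law: ALL, eps_max: 0.68}
  - {level: C1-C2, type: JC,     f_max: 314.0, d_max: 9.3,  law: CL,  eps_max: 2.11}
  - {level: C1-C2, type: LF,     f_max: 111.0, d_max: 9.6,  law: LF,  eps_max: 0.91}
  - {level: OC-C2, type: TM,     f_max: 76.0,  d_max: 11.9, law: PLL, eps_max: 0.41}
  - {level: OC-C2, type: Apical, f_max: 214.0, d_max: 8.0,  law: ISL, eps_max: 0.36}
  - {level: OC-C2, type: Alar,   f_max: 357.0, d_max: 14.1, law: ISL, eps_max: 2.20}
  - {level: OC-C2, type: CLV,    f_max: 436.0, d_max: 12.5, law: CL,  eps_max: 1.60}
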