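# Default anthropometric table (standard cadaver-study segment parameters,
# Winter's "Biomechanics and Motor Control of Human Movement" convention).
# Per segment:
#   mass_fraction          mass / whole-body mass
#   com_fraction_proximal  COM position / segment length, from the proximal joint
#   gyration_fraction      radius of gyration about the COM / segment length
# The trunk entry is the head-arms-trunk (HAT) lump measured from the greater
# trochanter (hip) towards the glenohumeral joint (shoulder), so the seven
# modelled segments account for the full body mass:
#   2*(0.0145 + 0.0465 + 0.100) + 0.678 = 1.000
foot:
  mass_fraction: 0.0145
  com_fraction_proximal: 0.50
  gyration_fraction: 0.475
shank:
  mass_fraction: 0.0465
  com_fraction_proximal: 0.433
  gyration_fraction: 0.302
thigh:
  mass_fraction: 0.100
  com_fraction_proximal: 0.433
  gyration_fraction: 0.323
trunk:
  mass_fraction: 0.678
  com_fraction_proximal: 0.626
  gyration_fraction: 0.496
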