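# Default tissue properties for the tumor-in-muscle phantom.
# density kg/m^3, specific_heat J/(kg K), conductivity W/(m K),
# electrical_conductivity S/m, relative_permeability (-), relative_permittivity (-)
muscle:
  density: 1090.0
  specific_heat: 3421.0
  conductivity: 0.49
  electrical_conductivity: 0.23
  relative_permeability: 1.0
  relative_permittivity: 2000.0
tumor:
  density: 1045.0
  specific_heat: 3760.0
  conductivity: 0.51
  electrical_conductivity: 0.23
  relative_permeability: 1.0
  relative_permittivity: 2000.0
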