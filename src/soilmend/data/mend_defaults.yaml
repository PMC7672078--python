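# Default non-calibrated constants of the soil-carbon model.
# Units: rates h^-1 (V's per unit enzyme C), concentrations mg C cm^-3 soil,
# activation energies kJ mol^-1, temperatures degC.
decomposition:
  VP1: 2.5
  VP2: 5.0
  VM: 1.0
  KP1: 50.0
  KP2: 25.0
  KM: 25.0
sorption:
  Kads: 0.006
  Kdes: 0.001
  Qmax: 1.7
partitioning:
  fD: 0.5
  gD: 0.5
microbes:
  rM: 0.002
  beta: 0.001
enzymes:
  pEP1: 1.0e-5
  pEP2: 1.0e-5
  pEM: 1.3e-5
  rE: 1.0e-3
temperature:
  Ea_V: 47.0
  Ea_K: 10.0
  Ea_ads: 5.0
  kYg: -0.01
  Tref: 20.0
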