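# Photosynthesis-irradiance parameter sets per symbiont photo-physiology.
# P_max relative units; E_opt in umol photons m^-2 s^-1. Values assumed
# (PAM-derived study values are supplementary, not printed); shallow E_opt
# exceeds mesophotic E_opt, as expected for high- vs low-light acclimated
# symbionts. Override via config.
shallow:
  P_max: 1.0
  E_opt: 300.0
mesophotic:
  P_max: 0.8
  E_opt: 80.0
irradiance:
  high: 750.0   # umol photons m^-2 s^-1, ~5 m depth
  low: 45.0     # umol photons m^-2 s^-1, ~50 m depth
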