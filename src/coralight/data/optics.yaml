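# Optical scenario ledger. Coefficients in cm^-1; entries are reduced
# scattering (mus_prime) and are converted to mus = mus'/(1-g) at load time.
# Scenario 1 is the default bio-optical parameter set; scenarios 2-6 vary
# one property at a time. Water values are assumed (clear seawater).
g: 0.9
water:
  mua: 0.001
  mus_prime: 0.01   # mus = 0.1 cm^-1 at g = 0.9
scenarios:
  1:
    name: default
    tissue: {mua: 1.18, mus_prime: 10.0}
    skeleton: {mua: 0.01, mus_prime: 15.0}
  2:
    name: reduced_pigmentation
    tissue: {mua: 0.59, mus_prime: 10.0}
    skeleton: {mua: 0.01, mus_prime: 15.0}
  3:
    name: enhanced_pigmentation
    tissue: {mua: 11.8, mus_prime: 10.0}
    skeleton: {mua: 0.01, mus_prime: 15.0}
  4:
    name: low_tissue_scattering
    tissue: {mua: 1.18, mus_prime: 1.0}
    skeleton: {mua: 0.01, mus_prime: 15.0}
  5:
    name: high_skeletal_absorption
    tissue: {mua: 1.18, mus_prime: 10.0}
    skeleton: {mua: 1.0, mus_prime: 15.0}   # value assumed (100x default)
  6:
    name: low_skeletal_scattering
    tissue: {mua: 1.18, mus_prime: 10.0}
    skeleton: {mua: 0.01, mus_prime: 3.0}
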