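# Default corallite-scale trait means (mm unless noted) for the two
# Stylophora pistillata morphotypes. provenance: "printed" = anchored to a
# value stated in the main text of the study this package models;
# "assumed" = plausible fixture value (supplementary tables not printed),
# override via config.
shallow:
  CD: 1.02          # calyx diameter; printed range 0.848-1.191 mm (midpoint)
  TH: 0.50          # theca (corallite wall) height; assumed
  SL: 0.25          # septal length; assumed
  SW: 0.06          # septal width; assumed
  CH: 0.15          # columella height; assumed
  SS: 0.30          # coenosteal spine spacing; assumed
  SPL: 0.12         # coenosteal spine length; assumed
  SPW: 0.06         # coenosteal spine width; assumed
  CSC: 1.30         # corallite center-to-center spacing; assumed (no depth effect printed)
  CSM: 0.24         # minimal corallite margin spacing; assumed magnitude
  branch_thickness: 6.0   # mm; assumed (printed: ~30% thinner at depth)
  porosity: 0.0828        # fraction; printed 8.28 +/- 0.01 %
mesophotic:
  CD: 0.63          # printed range 0.533-0.719 mm (midpoint); ~60% smaller than shallow
  TH: 0.25          # assumed (corallites shallower at depth)
  SL: 0.15          # assumed
  SW: 0.05          # assumed
  CH: 0.15          # assumed (no depth effect printed)
  SS: 0.22          # assumed (spines more closely spaced at depth)
  SPL: 0.08         # assumed (spines shorter at depth)
  SPW: 0.05         # assumed
  CSC: 1.40         # assumed (needs CSM <= CSC - CD after spacing exchange)
  CSM: 0.38         # printed ratio: 58% more spaced than shallow (0.24 * 1.58)
  branch_thickness: 4.2   # assumed from printed ~30% reduction
  porosity: 0.1557        # fraction; printed 15.57 +/- 0.01 %
provenance:
  printed: [CD, CSM, porosity, branch_thickness]
  assumed: [TH, SL, SW, CH, SS, SPL, SPW, CSC]
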