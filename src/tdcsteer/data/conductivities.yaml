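# Default tissue conductivities (S/m), measurements reported below 1 kHz.
# Anisotropic tissues carry a longitudinal/transverse pair.
air:
  sigma: 0.0
skin:
  sigma: 0.43
cerebrospinal_fluid:
  sigma: 1.8
sclera:
  sigma: 0.5
cortical_bone:
  sigma: 5.52e-3
cancelous_bone:
  sigma: 21.4e-3
muscle:
  sigma: 0.16
fat:
  sigma: 0.025
blood:
  sigma: 0.67
white_matter:
  sigma_longitudinal: 1.2
  sigma_transverse: 0.12
  anisotropic: true
gray_matter:
  sigma: 0.1
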