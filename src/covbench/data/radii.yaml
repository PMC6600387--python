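# Atomic radii (A) used in the rolling-probe solvent-accessible surface
# area calculation.  Values follow the Chothia (1976) set commonly used for
# protein SASA; editable config — absolute areas depend on this choice.
probe_radius: 1.4
radii:
  H: 1.00
  C: 1.87
  N: 1.65
  O: 1.40
  S: 1.85
  P: 1.90
  SE: 1.90
  default: 1.80
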