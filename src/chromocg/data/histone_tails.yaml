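# Disorder annotations for the packaged histone sequences, version 1.0.
# Residue ranges are 1-based inclusive; everything not listed as a tail is
# globular.  These follow common convention and are config-overridable.
H3:
  n_tail: [1, 44]
H4:
  n_tail: [1, 25]
H2A:
  n_tail: [1, 15]
  c_tail: [118, 129]
H2B:
  n_tail: [1, 30]
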