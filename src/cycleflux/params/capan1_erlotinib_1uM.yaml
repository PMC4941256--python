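# Capan-1, 1 uM erlotinib, 48 h exposure (0-48 h).  SYNTHETIC/NOMINAL:
# the published estimates for this cell line appear only graphically, so
# magnitudes here are nominal values consistent with the described model
# structure: a moderate G1 block on generation-1 cells only, released at
# the end of treatment, with regular progression through the other phases.
name: erlotinib
concentration: 1 uM
cell_line: Capan-1
modules:
  - name: block_G1_g1
    effect: block
    phase: G1
    generations: [1]
    magnitude: 0.35
    window: during
    profile: {kind: constant}
  - name: recycle_G1_g1
    effect: recycle
    phase: G1
    generations: [1]
    magnitude: 0.15
    window: always
    profile: {kind: sigmoid, half_max: 48.0, rise: 24.0}
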