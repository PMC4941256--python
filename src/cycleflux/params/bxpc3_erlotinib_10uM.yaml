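# BxPC-3, 10 uM erlotinib, 48 h exposure (0-48 h).
# Best-fit single-treatment model.  The generation-0 G1 blocking probability
# is a nominal value (the published table reports only the generation-1 G1
# block at this concentration); all other magnitudes are published estimates.
name: erlotinib
concentration: 10 uM
cell_line: BxPC-3
modules:
  - name: delay_S_g0
    effect: delay
    phase: S
    generations: [0]
    magnitude: 0.93
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: block_G1_g0
    effect: block
    phase: G1
    generations: [0]
    magnitude: 0.60   # nominal
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: block_G2M_g0
    effect: block
    phase: G2M
    generations: [0]
    magnitude: 0.23
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: block_G1_g1
    effect: block
    phase: G1
    generations: [1]
    magnitude: 0.98
    window: during
    profile: {kind: constant}
  - name: delay_S_g1
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.0
    window: during
    profile: {kind: constant}
  - name: death_S_g01
    effect: death
    phase: S
    generations: [0, 1]
    magnitude: 0.014
    window: during
    profile: {kind: constant}
  - name: delay_S_g1_post
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.41
    window: post
    profile: {kind: constant}
  - name: delay_G2M_g1_post
    effect: delay
    phase: G2M
    generations: [1]
    magnitude: 0.28
    window: post
    profile: {kind: constant}
  - name: recycle_G1_g01
    effect: recycle
    phase: G1
    generations: [0, 1]
    magnitude: 0.24
    window: always
    profile: {kind: sigmoid, half_max: 48.0, rise: 24.0}
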