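# BxPC-3, 1 uM erlotinib, 48 h exposure (0-48 h).
# Best-fit single-treatment model.  Generation-0 delay/block activities are
# time-dependent (sigmoid, half-maximum 6 h after drug addition); generation-1
# activities are constant during exposure.  After washout, blocked cells
# re-enter the cycle at a first-order recycling rate whose sigmoid reaches
# half-maximum at the end of treatment (48 h).
name: erlotinib
concentration: 1 uM
cell_line: BxPC-3
modules:
  - name: delay_S_g0
    effect: delay
    phase: S
    generations: [0]
    magnitude: 0.33
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: block_G2M_g0
    effect: block
    phase: G2M
    generations: [0]
    magnitude: 0.11
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: block_G1_g1
    effect: block
    phase: G1
    generations: [1]
    magnitude: 0.23
    window: during
    profile: {kind: constant}
  - name: delay_S_g1
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.33
    window: during
    profile: {kind: constant}
  - name: death_S_g01
    effect: death
    phase: S
    generations: [0, 1]
    magnitude: 0.010
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
    magnitude: 0.19
    window: post
    profile: {kind: constant}
  - name: recycle_G1_g01
    effect: recycle
    phase: G1
    generations: [0, 1]
    magnitude: 0.03
    window: always
    profile: {kind: sigmoid, half_max: 48.0, rise: 24.0}
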