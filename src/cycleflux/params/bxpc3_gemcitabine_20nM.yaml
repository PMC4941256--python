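# BxPC-3, 20 nM gemcitabine, 6 h exposure (0-6 h).
# Best-fit single-treatment model.  DNA synthesis is immediately inhibited
# by 88% (S-phase transit speed reduced to 12% of control in generations 0
# and 1) and recovers with a falling sigmoid, half-maximum 18 h after drug
# addition; recovery is complete (zero long-term S delay) at this
# concentration.  A strong G1 delay acts on generation 0 for the first 6 h,
# and a modest G2M block appears after 12 h.  No cell death.
name: gemcitabine
concentration: 20 nM
cell_line: BxPC-3
modules:
  - name: delay_G1_g0
    effect: delay
    phase: G1
    generations: [0]
    magnitude: 0.75
    window: always
    profile: {kind: step_window, onset: 0.0, offset: 6.0}
  - name: syninh_S_g01
    effect: synthesis_inhibition
    phase: S
    generations: [0, 1]
    magnitude: 0.88
    window: always
    profile: {kind: sigmoid, half_max: 18.0, rise: 12.0, direction: fall}
  - name: delay_S_g0_long
    effect: delay
    phase: S
    generations: [0]
    magnitude: 0.0
    window: always
    profile: {kind: step_window, onset: 18.0}
  - name: block_G2M_g0
    effect: block
    phase: G2M
    generations: [0]
    magnitude: 0.10
    window: always
    profile: {kind: step_window, onset: 12.0}
  - name: delay_S_g1_long
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.0
    window: always
    profile: {kind: step_window, onset: 21.0}
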