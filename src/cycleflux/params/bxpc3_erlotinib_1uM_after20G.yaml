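# BxPC-3, erlotinib 1 uM given 24-72 h after 20 nM gemcitabine (0-6 h):
# the corrected erlotinib model of the 20G->1E sequence.  Relative to the
# single-treatment 1 uM model: the generation-0 S delay is dropped (not in
# the combined model), the during-treatment generation-1 S delay weakens to
# 0.15, S-phase death vanishes, and the post-treatment S and G2M delays are
# potentiated (0.41 -> 0.58 and 0.19 -> 0.59); recycling 0.07/h.
# Module profiles are relative to the start of the erlotinib interval.
name: erlotinib
concentration: 1 uM (after 20 nM gemcitabine)
cell_line: BxPC-3
modules:
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
    magnitude: 0.15
    window: during
    profile: {kind: constant}
  - name: death_S_g01
    effect: death
    phase: S
    generations: [0, 1]
    magnitude: 0.0
    window: during
    profile: {kind: constant}
  - name: delay_S_g1_post
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.58
    window: post
    profile: {kind: constant}
  - name: delay_G2M_g1_post
    effect: delay
    phase: G2M
    generations: [1]
    magnitude: 0.59
    window: post
    profile: {kind: constant}
  - name: recycle_G1_g01
    effect: recycle
    phase: G1
    generations: [0, 1]
    magnitude: 0.07
    window: always
    profile: {kind: sigmoid, half_max: 48.0, rise: 24.0}
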