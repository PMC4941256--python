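# BxPC-3, 40 nM gemcitabine, 6 h exposure (0-6 h).
# Best-fit single-treatment model.  Complete immediate DNA synthesis
# inhibition with incomplete recovery (long-term S delay 0.37 in generation
# 0, 0.18 in generation 1); G1 delay on generation 0 up to 15 h; modest G2M
# block after 12 h.  Death-commitment windows: cells still traversing S in
# generation 0 after 48 h, or in generation 1 after 72 h, die at a nominal
# first-order rate (the published death rates are shown only graphically).
name: gemcitabine
concentration: 40 nM
cell_line: BxPC-3
modules:
  - name: delay_G1_g0
    effect: delay
    phase: G1
    generations: [0]
    magnitude: 0.87
    window: always
    profile: {kind: step_window, onset: 0.0, offset: 15.0}
  - name: syninh_S_g01
    effect: synthesis_inhibition
    phase: S
    generations: [0, 1]
    magnitude: 1.0
    window: always
    profile: {kind: sigmoid, half_max: 18.0, rise: 12.0, direction: fall}
  - name: delay_S_g0_long
    effect: delay
    phase: S
    generations: [0]
    magnitude: 0.37
    window: always
    profile: {kind: step_window, onset: 18.0}
  - name: block_G2M_g0
    effect: block
    phase: G2M
    generations: [0]
    magnitude: 0.15
    window: always
    profile: {kind: step_window, onset: 12.0}
  - name: delay_S_g1_long
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.18
    window: always
    profile: {kind: step_window, onset: 21.0}
  - name: death_S_g0_late
    effect: death
    phase: S
    generations: [0]
    magnitude: 0.02   # nominal
    window: always
    profile: {kind: step_window, onset: 48.0}
  - name: death_S_g1_late
    effect: death
    phase: S
    generations: [1]
    magnitude: 0.02   # nominal
    window: always
    profile: {kind: step_window, onset: 72.0}
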