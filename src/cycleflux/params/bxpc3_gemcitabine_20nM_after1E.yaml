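# BxPC-3, gemcitabine 20 nM given 66-72 h after 1 uM erlotinib (0-48 h):
# the corrected gemcitabine model of the 1E->20G sequence.  Relative to the
# single-treatment 20 nM model: the G1 delay saturates at 1, the acute
# S-synthesis inhibition softens to 0.68 while a strong long-term S delay
# appears in generation 0 (0 -> 0.54) and generation 1 (0 -> 0.23), and
# the late G2M block is potentiated (0.10 -> 0.60).
# Module profiles are relative to the start of the gemcitabine interval.
name: gemcitabine
concentration: 20 nM (after 1 uM erlotinib)
cell_line: BxPC-3
modules:
  - name: delay_G1_g0
    effect: delay
    phase: G1
    generations: [0]
    magnitude: 1.0
    window: always
    profile: {kind: step_window, onset: 0.0, offset: 6.0}
  - name: syninh_S_g01
    effect: synthesis_inhibition
    phase: S
    generations: [0, 1]
    magnitude: 0.68
    window: always
    profile: {kind: sigmoid, half_max: 18.0, rise: 12.0, direction: fall}
  - name: delay_S_g0_long
    effect: delay
    phase: S
    generations: [0]
    magnitude: 0.54
    window: always
    profile: {kind: step_window, onset: 18.0}
  - name: block_G2M_g0
    effect: block
    phase: G2M
    generations: [0]
    magnitude: 0.60
    window: always
    profile: {kind: step_window, onset: 12.0}
  - name: delay_S_g1_long
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.23
    window: always
    profile: {kind: step_window, onset: 21.0}
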