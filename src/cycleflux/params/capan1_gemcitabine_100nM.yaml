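# Capan-1, 100 nM gemcitabine, 6 h exposure (0-6 h).
# The 95% DNA-synthesis-rate reduction is the published estimate; the G1
# delay mirrors the high-dose behaviour of the other line (active up to
# 15 h), the late G2M block is a secondary effect present only at this
# concentration, and a residual long-term S delay remains (nominal
# magnitudes where only graphical values were published).  Purely
# cytostatic: no death modules.
name: gemcitabine
concentration: 100 nM
cell_line: Capan-1
modules:
  - name: delay_G1_g0
    effect: delay
    phase: G1
    generations: [0]
    magnitude: 0.87   # nominal
    window: always
    profile: {kind: step_window, onset: 0.0, offset: 15.0}
  - name: syninh_S_g01
    effect: synthesis_inhibition
    phase: S
    generations: [0, 1]
    magnitude: 0.95
    window: always
    profile: {kind: sigmoid, half_max: 18.0, rise: 12.0, direction: fall}
  - name: delay_S_g0_long
    effect: delay
    phase: S
    generations: [0]
    magnitude: 0.30   # nominal
    window: always
    profile: {kind: step_window, onset: 18.0}
  - name: block_G2M_g0
    effect: block
    phase: G2M
    generations: [0]
    magnitude: 0.15   # nominal
    window: always
    profile: {kind: step_window, onset: 12.0}
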