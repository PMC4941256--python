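# Capan-1, 30 nM gemcitabine, 6 h exposure (0-6 h).
# The 23% DNA-synthesis-rate reduction is the published estimate; restart
# kinetics match the other line (half-maximum at 18 h).  The short G1
# delay magnitude is nominal (reported only graphically).  No cell death.
name: gemcitabine
concentration: 30 nM
cell_line: Capan-1
modules:
  - name: delay_G1_g0
    effect: delay
    phase: G1
    generations: [0]
    magnitude: 0.40   # nominal
    window: always
    profile: {kind: step_window, onset: 0.0, offset: 6.0}
  - name: syninh_S_g01
    effect: synthesis_inhibition
    phase: S
    generations: [0, 1]
    magnitude: 0.23
    window: always
    profile: {kind: sigmoid, half_max: 18.0, rise: 12.0, direction: fall}
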