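# Capan-1, 10 uM erlotinib, 48 h exposure (0-48 h).  SYNTHETIC/NOMINAL:
# magnitudes are nominal values consistent with the described model
# structure: stronger G1 and S perturbations, reduced generation-0
# progression, only a very small G2M interception, a G1 block on
# generation-1 cells progressively released after washout, and a slight
# post-treatment S delay in generation 1.  Purely cytostatic (no death).
name: erlotinib
concentration: 10 uM
cell_line: Capan-1
modules:
  - name: delay_G1_g0
    effect: delay
    phase: G1
    generations: [0]
    magnitude: 0.40
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: delay_S_g0
    effect: delay
    phase: S
    generations: [0]
    magnitude: 0.50
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: block_G2M_g0
    effect: block
    phase: G2M
    generations: [0]
    magnitude: 0.05
    window: during
    profile: {kind: sigmoid, half_max: 6.0, rise: 6.0}
  - name: block_G1_g1
    effect: block
    phase: G1
    generations: [1]
    magnitude: 0.70
    window: during
    profile: {kind: constant}
  - name: delay_S_g1_post
    effect: delay
    phase: S
    generations: [1]
    magnitude: 0.20
    window: post
    profile: {kind: constant}
  - name: recycle_G1_g01
    effect: recycle
    phase: G1
    generations: [0, 1]
    magnitude: 0.12
    window: always
    profile: {kind: sigmoid, half_max: 48.0, rise: 24.0}
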