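# cycleflux

Age- and generation-structured modelling of how anticancer drugs perturb
the cell cycle, for quantitative pharmacologists and systems biologists
who work with flow-cytometry (FC) and time-lapse (TL) time courses.

Cytotoxicity assays summarize a drug's effect in one number; FC and TL
time courses contain far more — which checkpoint arrested the cells, for
how long, in which division generation, and who died.  `cycleflux`
extracts that information by simulating the flux of cells through
G1 → S → G2M and successive generations and fitting typed perturbation
modules to the data:

* **population engine** — continuity equations on an age grid per
  (phase, generation): gamma transit-time laws T̄_p, CV_p; checkpoint
  blocks with probability p; blocked pools with first-order recycling
  rates; per-hour death rates; fractional transit delays (an S-phase
  delay d is a DNA-synthesis-rate reduction by d).  A stochastic
  single-cell microsimulator provides an independent cross-check.
* **joint fitting** — weighted least squares over FC percentages
  (%G1/%S/%G2M), per-generation TL counts and absolute cell numbers;
  multi-start Nelder–Mead, residual-bootstrap intervals, F-tests for
  nested model refinement.
* **sequential combinations** — the population state is handed from the
  first drug's model to the second's at the switch time; deviations of
  combination data from this no-interaction expectation are localized by
  refitting selected parameters.
* **Loewe additivity** — 4PL ray fits of factorial SRB growth-inhibition
  grids, IC30/IC50 isoboles and the Combination Index
  CI = a/ICx_A + b/ICx_B (CI < 1 synergy, ≈ 1 additive, > 1 antagonism).
* **synthetic data** — generators that emulate the four data streams with
  realistic replicate structure, so every stage is testable end-to-end.

The shipped parameter library encodes published best-fit models for
erlotinib and gemcitabine on the pancreatic cancer lines BxPC-3 and
Capan-1 (YAML files under `src/cycleflux/params/`; nominal values are
marked where only graphical estimates exist).

## Worked example

Simulate 6 h of 20 nM gemcitabine on BxPC-3, generate a noisy synthetic
experiment from it, and refit the DNA-synthesis inhibition:

```python
import cycleflux as cf
from cycleflux import library

params = library.load_cell_line("BxPC-3")
gem = library.load_drug_model("bxpc3_gemcitabine_20nM")
sched = library.single_drug_schedule("gemcitabine", 0, 6)

series = cf.synthetic_data.simulate_observables(params, [gem], sched)
i24 = list(series.times).index(24.0)
print(f"%S at 24 h: {series.pct_S[i24]:.1f} (untreated {series.pct_S[0]:.1f})")

data = cf.generate_dataset(params, [gem], sched, seed=42)
skeleton = gem.copy()
skeleton.module("syninh_S_g01").magnitude = 0.5   # forget the truth
spec = cf.ParameterSpec("syn_inh", ("gemcitabine/syninh_S_g01",))
result = cf.fit(data, params, [skeleton], sched, [spec], seed=3, n_starts=4)
print(f"recovered S-synthesis inhibition: {result.estimates['syn_inh']:.3f}")
```

prints

```
%S at 24 h: 61.1 (untreated 34.1)
recovered S-synthesis inhibition: 0.880
```

— the 6 h pulse arrests DNA synthesis almost completely, piling a
semi-synchronized wave of cells into S phase by 24 h (%S rises from 34%
to 61%), and refitting the synthetic data recovers the generating
inhibition of 0.88 to three figures.

The same pipeline is scriptable from the shell:

```
cycleflux synth --model bxpc3_gemcitabine_20nM --schedule gemcitabine:0-6 \
                --out ds.csv --seed 42
cycleflux fit --data ds.csv --model bxpc3_gemcitabine_20nM \
              --schedule gemcitabine:0-6 --free gemcitabine/syninh_S_g01 \
              --out fit.json
```

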