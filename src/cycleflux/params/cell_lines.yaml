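# Unperturbed cycling parameters per cell line.
# Mean phase durations (hours) and coefficients of variation of the gamma
# transit-time laws.  These are nominal, documented values calibrated to
# typical exponential-growth behaviour of the two lines (mean cycle times
# of ~21.5 h for BxPC-3 and ~26 h for Capan-1, four generations reachable
# within 96 h); they are the ground truth used by the synthetic-data
# generator, not published estimates.
BxPC-3:
  mean_G1: 9.0
  mean_S: 8.0
  mean_G2M: 4.5
  cv_G1: 0.25
  cv_S: 0.15
  cv_G2M: 0.25
  max_generation: 5
Capan-1:
  mean_G1: 12.0
  mean_S: 9.0
  mean_G2M: 5.0
  cv_G1: 0.25
  cv_S: 0.15
  cv_G2M: 0.25
  max_generation: 5
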