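# Alternate parameter set: a more specific cytologist (sp = 0.99), shorter
# setup times, and a direct hourly total of $310/hr for complex-procedure
# ROSE instead of the composed c_var_o + c_var_c.  Useful for checking how
# conclusions shift under these alternative assumptions.
name: paper-prose-variant
description: >-
  Variant assumptions: sp 0.99, setup 3 min (simple) / 20 min (complex),
  complex ROSE variable-rate total fixed at $310/hr.
cytologist:
  sn: {base: 0.95, low: 0.90, high: 1.00}
  sp: {base: 0.99, low: 0.95, high: 1.00}
adequacy_levels:
  low: {base: 0.3, low: 0.2, high: 0.4}
  high: {base: 0.6, low: 0.5, high: 0.7}
stopping_rules:
  n_F: {base: 3, low: 2, high: 5}
  n_R: {base: 1, low: 1, high: 2}
shared:
  t_pass_F_min: {base: 2, low: 1, high: 3}
  t_pass_R_min: {base: 9, low: 6, high: 12}
  c_var_c_per_hr: {base: 100, low: 75, high: 125}
  c_pat_per_hr: {base: 20, low: 15, high: 25}
procedure_types:
  simple:
    rose_adds_cytologist: false
    t_setup_min: {base: 3, low: 3, high: 5}
    c_var_o_per_hr: {base: 30, low: 20, high: 40}
    c_np_per_pass: {base: 0, low: 0, high: 0}
    c_fixed: {base: 150, low: 100, high: 200}
  complex:
    rose_adds_cytologist: true
    c_var_R_total_per_hr: 310
    t_setup_min: {base: 20, low: 20, high: 30}
    c_var_o_per_hr: {base: 260, low: 190, high: 330}
    c_np_per_pass: {base: 30, low: 15, high: 45}
    c_fixed: {base: 300, low: 150, high: 450}
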