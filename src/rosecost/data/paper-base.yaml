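# Base catalogue configuration: two procedure types (simple = palpation
# guided, complex = image guided), two per-pass adequacy levels, and the
# enumerated stopping rules that span the 32-scenario experiment grid.
# Every parameter carries its base value and the plausible range used for
# one-way and probabilistic sensitivity analysis.  Key names carry units.
name: paper-base
description: >-
  Base values and sensitivity ranges for comparing ROSE against fixed-pass
  FNAB sampling across simple and complex procedure types.
cytologist:
  sn: {base: 0.95, low: 0.90, high: 1.00}
  sp: {base: 0.975, low: 0.95, high: 1.00}
adequacy_levels:
  low: {base: 0.3, low: 0.2, high: 0.4}
  high: {base: 0.6, low: 0.5, high: 0.7}
stopping_rules:
  # n_F enumerates 2..5 fixed passes; n_R enumerates 1..2 required adequate
  # calls.  These define scenario identity and are not drawn in PSA.
  n_F: {base: 3, low: 2, high: 5}
  n_R: {base: 1, low: 1, high: 2}
shared:
  t_pass_F_min: {base: 2, low: 1, high: 3}
  t_pass_R_min: {base: 9, low: 6, high: 12}
  c_var_c_per_hr: {base: 100, low: 75, high: 125}
  c_pat_per_hr: {base: 20, low: 15, high: 25}
procedure_types:
  simple:
    # The cytologist performs the aspiration themselves, so ROSE adds no
    # extra hourly rate: either protocol costs c_var_o + c_var_c per hour
    # ($130/hr at base, 95-165 across the component ranges).
    rose_adds_cytologist: false
    t_setup_min: {base: 4, low: 3, high: 5}
    c_var_o_per_hr: {base: 30, low: 20, high: 40}
    c_np_per_pass: {base: 0, low: 0, high: 0}
    c_fixed: {base: 150, low: 100, high: 200}
  complex:
    rose_adds_cytologist: true
    t_setup_min: {base: 30, low: 20, high: 30}
    c_var_o_per_hr: {base: 260, low: 190, high: 330}
    c_np_per_pass: {base: 30, low: 15, high: 45}
    c_fixed: {base: 300, low: 150, high: 450}
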