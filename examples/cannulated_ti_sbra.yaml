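# Cannulated 5/1.8 mm Ti6Al4V screw with a Monte-Carlo reliability block.
# Deterministic values are documented placeholders (see full_steel.yaml).
screw:
  catalog: "5.0-cannulated"
load:
  m_kg: 95.0
  k_m: 0.80
  k_dyn: 1.2
  n: 2.0
  alpha_deg: 50.0
beam:
  L_mm: 90.0
  L1_mm: 30.0
  L2_mm: 60.0
  k_N_per_m2: 2.0e+7
material:
  E_MPa: 110000.0
  Re_MPa: 880.0
sbra:
  n_draws: 100000
  seed: 2026
  variables:
    m_kg: {family: uniform, lo: 55.0, hi: 120.0}
    k_m: {family: uniform, lo: 0.78, hi: 0.82}
    k_dyn: {family: uniform, lo: 1.0, hi: 4.0}
    n: {family: uniform, lo: 2.0, hi: 3.0}
    alpha_deg: {family: uniform, lo: 5.0, hi: 80.0}
    Re_MPa: {family: uniform, lo: 800.0, hi: 960.0}
  hist_var: k_dyn
  hist_bins: 40
output:
  directory: out/cannulated_ti
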