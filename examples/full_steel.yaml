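# Solid 4.5 mm stainless-steel screw, 50 deg insertion, 90 mm length.
# Load split, foundation stiffness and force-transfer abscissae are
# documented placeholders chosen to give a realistic sub-critical case;
# they are not transcribed from any published input set.
screw:
  catalog: "4.5-full"
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
  E_MPa: 200000.0
  Re_MPa: 1000.0
output:
  directory: out/full_steel
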