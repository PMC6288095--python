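# Human parameter record (two-kidney baseline).
species_id: human
differs:
  N_nephrons: 2000000
  Na_in: 100.0        # mmol/day
  Wa_in: 2.0          # L/day
  L_pt: 14.0          # mm
  C_p: 7.0            # g/dl
  ECF_nom: 15.0       # L
conserved:
  C_glu_nom: 90.0
  C_Na: 140.0
  K_f0: 3.9
  K_albumin0: 0.0006
  RC_albumin: 2.5e-6
  D_eff: 11.0
  D_aff: 14.5
  D_pt: 27.0
  RT_G_nom: 180.0
  eta_pt_nonSGLT2: 0.76
resistance_anchors:
  R_prea: 14.0
  R_peri: 5.766
  R_rvr: 81.0
targets:
  MAP: 93.0
  CO: 5.0
  RBF: 1100.0
  GFR: 105.0
  SNGFR: 55.0
  P_gc: 60.0
  Na_ex: 100.0
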