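# Rat parameter record (two-kidney baseline).
species_id: rat
differs:
  N_nephrons: 50000
  Na_in: 2.0          # mmol/day
  Wa_in: 0.025        # L/day
  L_pt: 5.0           # mm
  C_p: 6.2            # g/dl
  ECF_nom: 0.055      # L (~18% of a 300 g body weight)
conserved:
  C_glu_nom: 90.0
  C_Na: 140.0
  K_f0: 3.9
  K_albumin0: 0.0006
  RC_albumin: 2.5e-6
  D_eff: 10.5
  D_aff: 14.0
  D_pt: 27.0
  RT_G_nom: 180.0
  eta_pt_nonSGLT2: 0.76
resistance_anchors:
  R_prea: 3500.0
  R_peri: 537.0
  R_rvr: 7275.0
targets:
  MAP: 103.0
  CO: 0.4
  RBF: 11.0
  GFR: 2.5
  SNGFR: 50.0
  P_gc: 42.0
  Na_ex: 2.0
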