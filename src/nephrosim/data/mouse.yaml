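# Mouse parameter record (two-kidney baseline).
species_id: mouse
differs:
  N_nephrons: 10000
  Na_in: 0.576        # mmol/day
  Wa_in: 0.005        # L/day
  L_pt: 2.2           # mm
  C_p: 3.4            # g/dl total plasma protein
  ECF_nom: 0.005      # L (not tabulated; ~20% of a 25 g body weight)
conserved:
  C_glu_nom: 90.0     # mg/dl
  C_Na: 140.0         # mmol/L
  K_f0: 3.9           # nl/min/mmHg per nephron
  K_albumin0: 0.0006
  RC_albumin: 2.5e-6  # mg/min per nephron
  D_eff: 10.5         # um
  D_aff: 14.0         # um
  D_pt: 27.0          # um
  RT_G_nom: 180.0     # mg/dl
  eta_pt_nonSGLT2: 0.76
resistance_anchors:   # printed "calculated" resistances, mmHg*min/L
  R_prea: 23000.0
  R_peri: 2700.0
  R_rvr: 58180.0
targets:              # observed/simulated phenotype (per-nephron SNGFR is the anchor)
  MAP: 98.0           # mmHg
  CO: 0.088           # L/min
  RBF: 1.8            # ml/min
  GFR: 0.3            # ml/min (printed; = SNGFR*N at printed precision)
  SNGFR: 29.0         # nl/min
  P_gc: 37.5          # mmHg
  Na_ex: 0.576        # mEq/day
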