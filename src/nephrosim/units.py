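"""Unit conversion constants.

Internal conventions:
  whole-animal flows        L/min
  per-nephron flows         nl/min
  pressures                 mmHg
  resistances               mmHg*min/L
  Na+ concentration         mmol/L
  glucose, threshold        mg/dl
  protein / albumin conc.   g/dl
  per-nephron solute rates  mmol/min (Na+), mg/min (glucose, albumin)
  simulation time           weeks
"""

NL_TO_L = 1e-9
NL_TO_ML = 1e-6
NL_TO_DL = 1e-8
MIN_PER_DAY = 1440.0
MIN_PER_WEEK = 10080.0
MG_PER_G = 1000.0

#: glucose molar mass, g/mol; mg/dl -> mmol/L is C/18
GLUCOSE_MW = 180.0
MGDL_TO_MMOLL = 10.0 / GLUCOSE_MW
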