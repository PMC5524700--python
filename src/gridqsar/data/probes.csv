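# Default single-site probe parameters for the five active-site chemotypes.
# Effective one-site parameters (charge in e, C6 in kcal*A^6/mol, C12 in
# kcal*A^12/mol); editable -- copy this file and pass your own table.
name,charge,c6,c12
O-H,0.40,437.0,318900.0
Ar(NH),0.35,755.0,980000.0
SH,0.10,1460.0,2900000.0
COO-,-1.00,350.0,230000.0
H2O,-0.82,595.0,582000.0
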