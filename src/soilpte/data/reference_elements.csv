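# Per-element reference values for the Hailun / Songnen Plain survey.
# background_mgkg: regional soil background (Songnen Plain), mg/kg
# screening_mgkg:  risk-control screening value (GB 15618-style), mg/kg
# toxicity_coeff:  Hakanson toxic-response coefficient (unitless)
# mdl_mgkg:        laboratory method detection limit, mg/kg
element,background_mgkg,screening_mgkg,toxicity_coeff,mdl_mgkg
As,9.14,40.00,10,0.6
Cd,0.073,0.30,30,0.01
Cr,42.46,150.00,2,2.79
Cu,17.78,50.00,5,0.85
Hg,0.031,1.30,40,0.0005
Ni,23.65,60.00,5,1.0
Pb,20.23,70.00,5,1.88
Zn,52.05,200.00,1,1.5
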