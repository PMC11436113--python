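# Descriptive statistics of the 304-sample Hailun survey (concentrations in
# mg/kg; pH unitless). Used to calibrate the synthetic generator and to
# evaluate indices at the study-mean concentrations.
variable,min,mean,max,median,sd,cv
As,5.56,11.16,16.88,11.13,1.32,0.12
Cd,0.06,0.11,0.47,0.10,0.04,0.36
Cr,51.15,65.29,75.84,65.45,3.46,0.05
Cu,17.72,22.56,28.71,22.48,1.32,0.06
Hg,0.02,0.03,0.08,0.03,0.01,0.30
Ni,22.51,27.07,30.94,27.03,1.46,0.05
Pb,21.18,26.09,57.30,25.74,2.84,0.11
Zn,51.66,66.01,106.81,65.93,4.52,0.07
pH,5.45,6.39,8.51,6.24,0.52,0.08
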