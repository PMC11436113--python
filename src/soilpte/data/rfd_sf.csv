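# USEPA-style toxicity values per exposure route.
# rfd_*: reference dose, mg/(kg*d). rfd_inhalation_lifetime applies to
# lifetime-averaged inhalation doses. sf_*: carcinogenic slope factor,
# (mg/(kg*d))^-1; available only for As and Cd. Empty cell = not available.
element,rfd_ingestion,rfd_dermal,rfd_inhalation,rfd_inhalation_lifetime,sf_ingestion,sf_dermal,sf_inhalation
As,3.0e-4,3.0e-4,3.52e-6,5.86e-6,1.5,1.5,4.3e-3
Cd,1.0e-3,2.5e-5,2.35e-6,3.91e-6,6.1,6.1,6.3
Cr,3.0e-3,7.5e-5,2.35e-5,3.91e-5,,,
Cu,4.0e-2,4.0e-2,,,,,
Hg,3.0e-4,2.1e-5,7.04e-5,1.17e-5,,,
Ni,2.0e-2,8.0e-4,2.11e-5,3.52e-5,,,
Pb,3.5e-3,5.3e-4,8.21e-5,1.37e-4,,,
Zn,3.0e-1,3.0e-1,,,,,
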