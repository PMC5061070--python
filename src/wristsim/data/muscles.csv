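name,pcsa_cm2,r_fe_mm,r_rud_mm,f_max_N
FCR,2.0,15.0,-5.0,50.0
FCU,3.4,17.0,14.0,85.0
ECRL,2.4,-10.0,-13.0,60.0
ECRB,2.9,-14.0,-4.0,72.5
ECU,2.6,-6.0,17.0,65.0
APL,1.9,-4.0,-15.0,47.5
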