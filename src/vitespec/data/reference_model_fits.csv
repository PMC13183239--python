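trait,cv,r2_cultivar,r2_random
E,34.83,0.19,0.28
A_max,15.35,,0.33
g_s,30.98,-0.02,-0.03
N,12.66,0.35,0.18
C,1.70,0.14,0.17
d13C,4.37,,
Psi_pd,24.95,-0.02,0.12
WUE_intr,29.32,0.09,0.04
WUE_inst,33.98,0.02,0.23
Area,22.76,0.26,0.13
LDMC,8.60,0.35,0.57
LMA,9.57,0.29,-0.01
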