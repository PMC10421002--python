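forest_type,row_kind,c_p97_5_mt,c_p2_5_mt,r_97_5_pct,r_2_5_pct
FIR-NF,type,0.26,1.79,-74,78
TSU-NF,type,2.33,9.62,-56,80
CYP-NF,type,6.01,9.60,-19,30
PIN-NF,type,5.22,10.75,-31,42
SPR-NF,type,0.73,2.69,-54,72
O-C-NF,type,3.20,7.19,-34,48
CYP-P,type,0.60,1.26,-32,43
PIN-P,type,2.06,4.58,-34,47
LF-P,type,1.47,3.34,-34,49
TAI-P,type,0.14,0.32,-35,48
JC-P,type,1.15,2.64,-35,48
TIC-P,type,0.07,0.15,-33,51
O-C-P,type,0.13,0.29,-35,45
MC-P,type,1.63,3.70,-46,21
B-NF,type,0.52,1.21,-35,50
MB-NF,type,33.18,77.95,-36,51
ACA-P,type,2.11,4.04,-29,36
SG-P,type,0.10,0.21,-36,43
CAM-P,type,0.13,0.29,-34,47
ASH-P,type,0.48,1.06,-34,47
JE-P,type,0.03,0.06,-34,47
SDT-P,type,0.29,0.67,-36,49
O-B-P,type,0.59,1.39,-35,51
MB-P,type,1.00,2.34,-35,51
M-CB-NF,type,22.31,40.10,-24,36
M-CB-P,type,1.63,3.70,-34,49
Total,total,110.07,159.59,-16,22
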