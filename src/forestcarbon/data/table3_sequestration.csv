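wood_type,regeneration,forest_type,row_kind,dc_a,dc_mt,proportion_pct
coniferous,nature,FIR-NF,type,0.40,0.01,0.2
coniferous,nature,TSU-NF,type,0.84,0.05,0.9
coniferous,nature,CYP-NF,type,1.33,0.07,1.3
coniferous,nature,PIN-NF,type,1.28,0.09,1.7
coniferous,nature,SPR-NF,type,1.88,0.01,0.3
coniferous,nature,O-C-NF,type,4.59,0.11,2.0
coniferous,nature,,subtotal,0.68,0.33,6.3
coniferous,plantation,CYP-P,type,1.85,0.05,0.9
coniferous,plantation,PIN-P,type,3.56,0.16,3.2
coniferous,plantation,LF-P,type,3.91,0.12,2.3
coniferous,plantation,TAI-P,type,2.33,0.01,0.2
coniferous,plantation,JC-P,type,2.00,0.09,1.8
coniferous,plantation,TIC-P,type,4.07,0.01,0.1
coniferous,plantation,O-C-P,type,6.22,0.01,0.2
coniferous,plantation,MC-P,type,3.59,0.16,3.1
coniferous,plantation,P-C-P,type,4.23,0.02,0.3
coniferous,plantation,NEW-C-P,type,4.15,<0.005,<0.05
coniferous,plantation,,subtotal,0.33,0.63,12.1
coniferous,,,wood_total,0.45,0.96,18.4
broadleaved,nature,B-NF,type,1.22,0.02,0.4
broadleaved,nature,MB-NF,type,1.74,1.26,24.1
broadleaved,nature,,subtotal,0.58,1.27,24.5
broadleaved,plantation,ACA-P,type,5.19,0.19,3.6
broadleaved,plantation,SG-P,type,2.34,0.01,0.2
broadleaved,plantation,CAM-P,type,2.20,0.01,0.2
broadleaved,plantation,ASH-P,type,3.46,0.05,0.9
broadleaved,plantation,JE-P,type,0.46,<0.005,<0.05
broadleaved,plantation,SDT-P,type,3.47,0.03,0.6
broadleaved,plantation,O-B-P,type,4.23,0.06,1.1
broadleaved,plantation,MB-P,type,3.78,0.10,1.9
broadleaved,plantation,P-B-P,type,3.44,1.72,33.1
broadleaved,plantation,NEW-B-P,type,3.23,0.01,0.2
broadleaved,plantation,,subtotal,0.28,2.18,41.9
broadleaved,,,wood_total,0.39,3.46,66.4
bamboo,nature,MAK-BAM-NF,type,0.98,0.01,0.2
bamboo,nature,MOS-BAM-NF,type,1.39,0.00,0.1
bamboo,nature,TG-BAM-NF,type,3.62,0.04,0.7
bamboo,nature,THO-BAM-NF,type,0.97,<0.005,<0.05
bamboo,nature,BAM-BAM-NF,type,1.04,<0.005,<0.05
bamboo,nature,O-BAM-NF,type,0.68,<0.005,<0.05
bamboo,nature,FAR-BAM-NF,type,0.97,0.02,0.3
bamboo,nature,,subtotal,0.61,0.07,1.4
bamboo,plantation,MAK-BAM-P,type,0.98,0.01,0.2
bamboo,plantation,MOS-BAM-P,type,1.37,0.00,0.1
bamboo,plantation,TG-BAM-P,type,3.64,0.03,0.5
bamboo,plantation,THO-BAM-P,type,0.97,0.01,0.2
bamboo,plantation,BAM-BAM-P,type,1.02,<0.005,<0.05
bamboo,plantation,O-BAM-P,type,0.86,<0.005,<0.05
bamboo,plantation,P-BAM-P,type,0.97,0.02,0.4
bamboo,plantation,,subtotal,0.73,0.07,1.4
bamboo,,,wood_total,0.68,0.14,2.8
mixed,nature,M-CB-NF,type,1.42,0.42,8.0
mixed,nature,M-BAMC-NF,type,5.45,<0.005,<0.05
mixed,nature,M-BAMB-NF,type,1.98,0.13,2.4
mixed,nature,M-BAMCB-NF,type,3.24,<0.005,<0.05
mixed,nature,,subtotal,0.66,0.55,10.5
mixed,plantation,M-CB-P,type,0.89,0.04,0.7
mixed,plantation,M-BAMC-P,type,2.08,<0.005,0.1
mixed,plantation,M-BAMB-P,type,1.93,0.05,0.9
mixed,plantation,M-BAMCB-P,type,2.40,0.01,0.2
mixed,plantation,P-M-CB-P,type,0.89,<0.005,<0.005
mixed,plantation,,subtotal,0.71,0.10,2.0
mixed,,,wood_total,0.66,0.65,12.5
,,,grand_total,0.44,5.21,100.0
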