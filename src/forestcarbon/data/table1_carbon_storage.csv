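wood_type,regeneration,forest_type,row_kind,c_a,c_mt,proportion_pct
coniferous,nature,FIR-NF,type,47.17,1.01,0.6
coniferous,nature,TSU-NF,type,98.94,5.34,3.2
coniferous,nature,CYP-NF,type,149.94,7.39,4.5
coniferous,nature,PIN-NF,type,107.41,7.55,4.6
coniferous,nature,SPR-NF,type,221.48,1.57,0.9
coniferous,nature,O-C-NF,type,210.12,4.87,2.9
coniferous,nature,,subtotal,123.03,27.73,16.7
coniferous,plantation,CYP-P,type,34.97,0.88,0.5
coniferous,plantation,PIN-P,type,67.28,3.11,1.9
coniferous,plantation,LF-P,type,74.08,2.24,1.4
coniferous,plantation,TAI-P,type,43.56,0.22,0.1
coniferous,plantation,JC-P,type,37.79,1.78,1.1
coniferous,plantation,TIC-P,type,78.38,0.10,0.1
coniferous,plantation,O-C-P,type,115.97,0.20,0.1
coniferous,plantation,MC-P,type,67.85,3.05,1.8
coniferous,plantation,P-C-P,type,79.64,0.32,0.2
coniferous,plantation,NEW-C-P,type,78.52,0.02,<0.05
coniferous,plantation,,subtotal,57.87,11.92,7.2
coniferous,,,wood_total,91.92,39.65,23.9
broadleaved,nature,B-NF,type,51.78,0.81,0.5
broadleaved,nature,MB-NF,type,71.80,51.79,31.3
broadleaved,nature,,subtotal,71.38,52.60,31.8
broadleaved,plantation,ACA-P,type,81.06,2.97,1.8
broadleaved,plantation,SG-P,type,35.61,0.15,0.1
broadleaved,plantation,CAM-P,type,34.42,0.20,0.1
broadleaved,plantation,ASH-P,type,54.04,0.72,0.4
broadleaved,plantation,JE-P,type,7.10,0.04,<0.05
broadleaved,plantation,SDT-P,type,53.88,0.45,0.3
broadleaved,plantation,O-B-P,type,66.31,0.92,0.6
broadleaved,plantation,MB-P,type,59.31,1.55,0.9
broadleaved,plantation,P-B-P,type,53.88,26.98,16.3
broadleaved,plantation,NEW-B-P,type,50.53,0.17,0.1
broadleaved,plantation,,subtotal,55.26,34.15,20.6
broadleaved,,,wood_total,64.02,86.75,52.4
bamboo,nature,MAK-BAM-NF,type,18.82,0.19,0.1
bamboo,nature,MOS-BAM-NF,type,26.77,0.05,<0.05
bamboo,nature,TG-BAM-NF,type,69.59,0.72,0.4
bamboo,nature,THO-BAM-NF,type,18.67,0.04,0.0
bamboo,nature,BAM-BAM-NF,type,20.36,<0.005,<0.05
bamboo,nature,O-BAM-NF,type,12.96,<0.005,<0.05
bamboo,nature,FAR-BAM-NF,type,18.73,0.34,0.2
bamboo,nature,,subtotal,31.33,1.36,0.8
bamboo,plantation,MAK-BAM-P,type,18.85,0.15,0.1
bamboo,plantation,MOS-BAM-P,type,26.29,0.08,<0.05
bamboo,plantation,TG-BAM-P,type,69.99,0.52,0.3
bamboo,plantation,THO-BAM-P,type,18.70,0.22,0.1
bamboo,plantation,BAM-BAM-P,type,19.66,0.02,<0.05
bamboo,plantation,O-BAM-P,type,16.52,0.01,<0.05
bamboo,plantation,P-BAM-P,type,18.72,0.41,0.2
bamboo,plantation,,subtotal,26.24,1.41,0.8
bamboo,,,wood_total,28.51,2.76,1.7
mixed,nature,M-CB-NF,type,100.20,29.47,17.8
mixed,nature,M-BAMC-NF,type,126.17,0.01,<0.05
mixed,nature,M-BAMB-NF,type,45.86,2.92,1.8
mixed,nature,M-BAMCB-NF,type,74.86,0.06,<0.05
mixed,nature,,subtotal,90.50,32.46,19.6
mixed,plantation,M-CB-P,type,62.99,2.49,1.5
mixed,plantation,M-BAMC-P,type,48.04,0.10,0.1
mixed,plantation,M-BAMB-P,type,44.55,1.13,0.7
mixed,plantation,M-BAMCB-P,type,55.43,0.30,0.2
mixed,plantation,P-M-CB-P,type,62.93,0.01,<0.05
mixed,plantation,,subtotal,55.53,4.03,2.4
mixed,,,wood_total,84.62,36.49,22.0
,,,grand_total,54.86,165.65,100.0
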