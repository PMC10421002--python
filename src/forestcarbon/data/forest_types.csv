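abbreviation,name,wood_type,regeneration,species_weights
FIR-NF,Natural Fir Forest,coniferous,nature,abies_kawakamii:1
TSU-NF,Natural Tsuga Forest,coniferous,nature,tsuga_chinensis:1
CYP-NF,Natural Cypress Forest,coniferous,nature,chamaecyparis_taiwanensis:0.5;chamaecyparis_formosensis:0.5
PIN-NF,Natural Pine Forest,coniferous,nature,pinus_taiwanensis:1
SPR-NF,Natural Spruce Forest,coniferous,nature,picea_morrisonicola:1
O-C-NF,Other Natural Coniferous Forest,coniferous,nature,mixed_conifer:1
CYP-P,Cypress Plantation,coniferous,plantation,chamaecyparis_taiwanensis:1
PIN-P,Pine Plantation,coniferous,plantation,pinus_massoniana:1
LF-P,Luanta Fir Plantation,coniferous,plantation,cunninghamia_konishii:1
TAI-P,Taiwania Plantation,coniferous,plantation,taiwania_cryptomerioides:1
JC-P,Japanese Cedar Plantation,coniferous,plantation,cryptomeria_japonica:1
TIC-P,Taiwan Incense Cedar Plantation,coniferous,plantation,calocedrus_formosana:1
O-C-P,Other Conifer Plantation,coniferous,plantation,mixed_conifer:1
MC-P,Mixed Conifer Plantation,coniferous,plantation,mixed_conifer:1
P-C-P,Private Coniferous Plantation,coniferous,plantation,mixed_conifer:1
NEW-C-P,Newly added Coniferous Plantation,coniferous,plantation,mixed_conifer:1
B-NF,Natural Broadleaved Forest,broadleaved,nature,mixed_broadleaf:1
MB-NF,Natural Mixed Broadleaved Forest,broadleaved,nature,mixed_broadleaf:1
ACA-P,Acacia Plantation,broadleaved,plantation,acacia_confusa:1
SG-P,Sweet Gum Plantation,broadleaved,plantation,liquidambar_formosana:1
CAM-P,Camphor Plantation,broadleaved,plantation,cinnamomum_camphora:1
ASH-P,Ash Plantation,broadleaved,plantation,fraxinus_griffithii:1
JE-P,Japanese elm Plantation,broadleaved,plantation,zelkova_serrata:1
SDT-P,Sapphire Dragon Tree Plantation,broadleaved,plantation,paulownia_kawakamii:1
O-B-P,Other Broadleaved Plantation,broadleaved,plantation,mixed_broadleaf:1
MB-P,Mixed Broadleaved Plantation,broadleaved,plantation,mixed_broadleaf:1
P-B-P,Private Broadleaved Plantation,broadleaved,plantation,mixed_broadleaf:1
NEW-B-P,Newly added Broadleaved Plantation,broadleaved,plantation,mixed_broadleaf:1
MAK-BAM-NF,Natural Makino Bamboo Forest,bamboo,nature,phyllostachys_makinoi:1
MOS-BAM-NF,Natural Moso Bamboo Forest,bamboo,nature,phyllostachys_pubescens:1
TG-BAM-NF,Natural Taiwan Giant Bamboo Forest,bamboo,nature,dendrocalamus_latiflorus:1
THO-BAM-NF,Natural Thorny Bamboo Forest,bamboo,nature,phyllostachys_makinoi:1
BAM-BAM-NF,Natural Bambusa Forest,bamboo,nature,phyllostachys_makinoi:1
FAR-BAM-NF,Natural Fargesia Forest,bamboo,nature,phyllostachys_makinoi:1
O-BAM-NF,Other Natural Bamboo Forest,bamboo,nature,phyllostachys_makinoi:1
MAK-BAM-P,Makino Bamboo Plantation,bamboo,plantation,phyllostachys_makinoi:1
MOS-BAM-P,Moso Bamboo Plantation,bamboo,plantation,phyllostachys_pubescens:1
TG-BAM-P,Taiwan Giant Bamboo Plantation,bamboo,plantation,dendrocalamus_latiflorus:1
THO-BAM-P,Thorny Bamboo Plantation,bamboo,plantation,phyllostachys_makinoi:1
BAM-BAM-P,Bambusa Plantation,bamboo,plantation,phyllostachys_makinoi:1
O-BAM-P,Other Bamboo Plantation,bamboo,plantation,phyllostachys_makinoi:1
P-BAM-P,Private Bamboo Plantation,bamboo,plantation,phyllostachys_makinoi:1
M-CB-NF,Natural Coniferous and Broadleaved Mixed Forest,mixed,nature,mixed_conifer:0.25;chamaecyparis_formosensis:0.25;chamaecyparis_taiwanensis:0.25;mixed_broadleaf:0.25
M-BAMC-NF,Natural Bamboo and Coniferous Mixed Forest,mixed,nature,phyllostachys_makinoi:0.5;mixed_conifer:0.5
M-BAMB-NF,Natural Bamboo and Broadleaved Mixed Forest,mixed,nature,phyllostachys_makinoi:0.5;mixed_broadleaf:0.5
M-BAMCB-NF,"Natural Bamboo, Coniferous and Broadleaved Mixed Forest",mixed,nature,phyllostachys_makinoi:0.5;mixed_conifer:0.25;mixed_broadleaf:0.25
M-CB-P,Coniferous and Broadleaved Mixed Plantation,mixed,plantation,mixed_conifer:0.5;mixed_broadleaf:0.5
M-BAMC-P,Bamboo and Coniferous Mixed Plantation,mixed,plantation,phyllostachys_makinoi:0.5;mixed_conifer:0.5
M-BAMB-P,Bamboo and Broadleaved Mixed Plantation,mixed,plantation,phyllostachys_makinoi:0.5;mixed_broadleaf:0.5
M-BAMCB-P,"Bamboo, Coniferous and Broadleaved Mixed Plantation",mixed,plantation,phyllostachys_makinoi:0.5;mixed_conifer:0.25;mixed_broadleaf:0.25
P-M-CB-P,Private Coniferous and Broadleaved Mixed Plantation,mixed,plantation,mixed_conifer:0.5;mixed_broadleaf:0.5
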