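name,group,formula,molecular_weight_da,diffusion_coefficient_m2_s
TEGDMA,Composite resins - tooth restoration,CH2=C(CH3)COO(CH2CH2O)3COC(CH3)=CH2,286,7.5e-10
HEMA,Bonding agents - tooth restoration,CH2=C(CH3)COOCH2CH2OH,130,9.7e-10
Fluoride ions,Glass ionomer cements - pulp protection,F-,9,2.4e-09
Eugenol,Zinc oxide-eugenol bases - pulp protection,C10H12O2,164,8.9e-10
Calcium ions,Calcium hydroxide-based liners - pulp protection,Ca++,20,1.8e-09
Silicon,Calcium silicate-based bases - pulp protection,Si4-,14,2.1e-09
Transforming growth factor-beta,EDTA-soluble dentinal constituents - pulp protection,Polypeptide,44300,1.4e-10
Bone morphogenetic protein 7,BMP7-containing capping agents - pulp protection,Polypeptide,50000,1.3e-10
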