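reaction,mechanism,slot,value,units
GlyDH,specific_activation,Kcat,0.0621,1/s
GlyDH,specific_activation,Km_a,6.15,mM
GlyDH,specific_activation,Ka,0.008,mM
hpaD,mm_competitive_product_inhibition_2s,Kcat,16.73,1/s
hpaD,mm_competitive_product_inhibition_2s,Km_a,0.39,mM
hpaD,mm_competitive_product_inhibition_2s,Km_b,1.3,mM
hpaD,mm_competitive_product_inhibition_2s,Ki_p,0.12,mM
McoaR,mm_2s_random_bibi_denominator,Kcat,50,1/s
McoaR,mm_2s_random_bibi_denominator,Km_a,0.3,mM
McoaR,mm_2s_random_bibi_denominator,Km_b,0.03,mM
MsaR,mm_2s_random_bibi_denominator,Kcat,115,1/s
MsaR,mm_2s_random_bibi_denominator,Km_a,0.07,mM
MsaR,mm_2s_random_bibi_denominator,Km_b,0.07,mM
BaTA,ping_pong_bibi_substrate_inhibition,Kcat,47.4,1/s
BaTA,ping_pong_bibi_substrate_inhibition,Km_a,5.8,mM
BaTA,ping_pong_bibi_substrate_inhibition,Km_b,1.07,mM
BaTA,ping_pong_bibi_substrate_inhibition,Ki_b,10.2,mM
hpcoaS,mm_3s_multiplicative,Kcat,36,1/s
hpcoaS,mm_3s_multiplicative,Km_a,0.015,mM
hpcoaS,mm_3s_multiplicative,Km_b,0.01,mM
hpcoaS,mm_3s_multiplicative,Km_c,0.05,mM
hpcoaDH,michaelis_menten_1s,Kcat,96,1/s
hpcoaDH,michaelis_menten_1s,Km,0.06,mM
AcoaTioE,michaelis_menten_1s,Kcat,0.55,1/s
AcoaTioE,michaelis_menten_1s,Km,0.167,mM
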