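reaction,mechanism,slot,value,units
G3pD,rapid_equilibrium_random_bibi_reversible,Km_a,0.175,mM
G3pD,rapid_equilibrium_random_bibi_reversible,Km_b,0.0037,mM
G3pD,rapid_equilibrium_random_bibi_reversible,Km_p,0.12,mM
G3pD,rapid_equilibrium_random_bibi_reversible,Km_q,0.165,mM
G3pD,rapid_equilibrium_random_bibi_reversible,Keq,900,dimensionless
G3pP,michaelis_menten_1s,Km,2.9,mM
GlyK,mm_2s_random_bibi_denominator,Km_a,0.0084,mM
GlyK,mm_2s_random_bibi_denominator,Km_b,0.0049,mM
GlyK,mm_2s_random_bibi_denominator,Kd_a,0.086,mM
AccC,ordered_bibi_product_inhibition,Km_a,0.018,mM
AccC,ordered_bibi_product_inhibition,Km_b,0.06,mM
AccC,ordered_bibi_product_inhibition,Ki_p,0.07,mM
GluD,mm_2s_multiplicative,Km_a,0.495,mM
GluD,mm_2s_multiplicative,Km_b,0.037,mM
AspAT,ping_pong_bibi_reversible,Km_a,19.07,mM
AspAT,ping_pong_bibi_reversible,Km_b,0.19,mM
AspAT,ping_pong_bibi_reversible,Km_p,0.437,mM
AspAT,ping_pong_bibi_reversible,Km_q,2.94,mM
AspAT,ping_pong_bibi_reversible,Keq,3.2,dimensionless
AspC,michaelis_menten_1s,Km,0.155,mM
GlyD,hill_2s,Km_a,47.83,mM
GlyD,hill_2s,Km_b,1.385,mM
GlyD,hill_2s,n,0.98,dimensionless
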