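,mM_per_s
PTS,0.004500000000000001
PFK,0.0045000000000000005
GAPDH,0.009000000000000003
PYK,0.002928549721261952
PDH,0.006491134873704532
POX,0.0009374148475574215
CS,0.0060002769480656665
AKGDH,0.006000276948065669
PPC,0.0015714502787380477
ANA_OAA,0.0015714502787380483
ANA_ACCOA,0.000490857925638863
OXPHOS,0.027491688769835862
ATPASE,0.06634989600462243
ADK,0.0
THD_f,0.005487120245432118
THD_r,0.005487120245432116
CDH_f,0.016920238491097823
CDH_r,0.015348788212359772
feed_GLCx,0.0045
vent_CO2,0.016920238491097823
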