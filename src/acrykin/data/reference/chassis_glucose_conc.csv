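,mM
GLCx,0.11485372378348736
GLYx,1e-09
G6P,0.012140034457612848
DAP,0.024512036187693025
PEP,0.22687122512407
PYR,0.09835128237444817
ACCOA,0.034504272476270845
OAA,0.09888474480120812
AKG,0.051114939526839556
CO2,1.692023849109782
HCO3,0.7674394106179886
COA,0.7654957275237301
NAD,1.5916259215238857
NADH,0.008374078476116154
NADP,0.13105012715326286
NADPH,0.06894987284673687
ATP,0.9858795089271754
ADP,2.4141204912121137
AMP,0.0
PI,10.0
NH4,10.0
BIOM,0.0
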