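reaction,fcc_structural,fcc_fd
PTS,1.3121033827293078e-17,3.330113974205775e-10
PFK,-6.5669360818694926e-18,-1.398834380417148e-10
GAPDH,2.277832873440741e-18,-1.4663336902023564e-10
PYK,-0.5112610649943062,-0.5112511488718078
PDH,0.061099908549736556,0.06110459329921987
POX,-0.053567642972461874,-0.05356592913565051
CS,0.026384254404201585,0.026386698794493287
AKGDH,-7.661101191968817e-16,7.528837487489628e-08
PPC,0.5813992078656236,0.5814111180309662
ANA_OAA,-0.015889733000016948,-0.015889120508183467
ANA_ACCOA,-0.021683755493674683,-0.021682919529214143
OXPHOS,6.414527878726605e-05,6.41794333247399e-05
ATPASE,-0.06318430768675914,-0.06328972386125646
ADK,-0.0,0.0
THD_f,-1.1709211049137747e-16,-1.8100961290038542e-08
THD_r,1.1709211049137745e-16,1.6781172153975127e-08
CDH_f,0.36262879562527645,0.36264111508332725
CDH_r,-0.32895000780774075,-0.3289420253659036
feed_GLCx,1.3255889958566105,1.3256491002997728
vent_CO2,-0.36262879562527645,-0.36261894516616905
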