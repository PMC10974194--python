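variety,yield_t_ha,culms_m2,spikes_m2,biomass_t_ha
SC,2.6,302,273,10.0
MZ,1.8,322,296,6.6
SL,2.0,258,231,7.7
MixD1,1.9,355,327,7.8
MixD2,2.1,388,340,8.6
MixD3,1.7,245,199,7.5
MixD4,1.7,324,314,7.2
PG,2.4,221,215,5.7
SV,3.5,272,264,7.6
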