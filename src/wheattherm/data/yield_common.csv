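variety,yield_t_ha,culms_m2,spikes_m2,biomass_t_ha
RS,2.1,380,364,6.5
RM,1.8,414,394,6.2
GR,2.2,377,352,7.7
MixC1,1.5,275,260,6.1
MixC2,1.5,298,275,6.2
MixC3,1.6,367,341,5.6
MixC4,2.1,360,367,6.4
AX,2.8,380,378,6.8
AL,3.0,492,485,6.8
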