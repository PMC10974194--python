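species,variety,wci_m,wci_sd
durum,SC,0.93,0.05
durum,MZ,0.78,0.04
durum,SL,0.91,0.04
durum,MixD1,0.70,0.03
durum,MixD2,0.71,0.03
durum,MixD3,0.63,0.04
durum,MixD4,0.61,0.04
durum,PG,0.83,0.04
durum,SV,0.92,0.05
common,RS,0.78,0.04
common,RM,0.80,0.04
common,GR,0.93,0.05
common,MixC1,0.65,0.03
common,MixC2,0.63,0.04
common,MixC3,0.64,0.04
common,MixC4,0.75,0.04
common,AX,0.83,0.05
common,AL,0.85,0.04
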