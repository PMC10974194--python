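species,variety,stem_elongation,heading_begins,milky_waxy,full_ripening,wsi_m
durum,SC,0.21,0.31,0.27,0.21,0.25
durum,MZ,0.16,0.19,0.23,0.17,0.19
durum,SL,0.18,0.22,0.23,0.19,0.20
durum,MixD1,0.14,0.20,0.21,0.16,0.18
durum,MixD2,0.18,0.24,0.24,0.19,0.21
durum,MixD3,0.15,0.19,0.17,0.14,0.16
durum,MixD4,0.14,0.17,0.18,0.13,0.15
durum,PG,0.23,0.31,0.28,0.23,0.26
durum,SV,0.24,0.32,0.33,0.26,0.29
common,RS,0.18,0.23,0.23,0.17,0.20
common,RM,0.17,0.25,0.21,0.18,0.20
common,GR,0.19,0.22,0.25,0.17,0.21
common,MixC1,0.12,0.18,0.17,0.13,0.15
common,MixC2,0.13,0.19,0.18,0.14,0.16
common,MixC3,0.12,0.17,0.16,0.15,0.15
common,MixC4,0.16,0.21,0.19,0.17,0.18
common,AX,0.18,0.21,0.30,0.19,0.22
common,AL,0.23,0.32,0.27,0.21,0.26
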