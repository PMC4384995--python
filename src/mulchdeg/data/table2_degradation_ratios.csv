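soil_id,week,mean_ratio_percent,se_percent
CHI,1,-2.4,2.5
CHI,2,-0.9,0.9
CHI,3,7.4,7.3
CHI,4,33.1,9.0
TKB,1,1.0,3.5
TKB,2,-0.7,1.3
TKB,3,0.8,1.5
TKB,4,1.4,3.4
HIO,1,-1.7,1.1
HIO,2,1.2,1.4
HIO,3,-0.2,0.2
HIO,4,7.3,8.1
MJO,1,0.6,1.7
MJO,2,0.6,3.0
MJO,3,4.0,2.0
MJO,4,7.9,1.8
TAK,1,1.8,2.5
TAK,2,3.3,1.7
TAK,3,5.4,3.2
TAK,4,30.1,6.6
KIB,1,-4.0,2.1
KIB,2,7.8,5.7
KIB,3,34.5,8.3
KIB,4,58.9,36.3
OKA,1,0.4,2.6
OKA,2,3.9,5.8
OKA,3,60.3,23.2
OKA,4,95.9,6.6
AKA,1,-4.7,2.5
AKA,2,0.5,2.3
AKA,3,54.3,22.9
AKA,4,66.0,17.3
MIY,1,1.2,0.2
MIY,2,5.2,3.2
MIY,3,28.5,27.7
MIY,4,69.7,33.2
YM1,1,2.7,0.9
YM1,2,16.9,3.4
YM1,3,62.0,14.1
YM1,4,48.5,11.6
YM2,1,0.9,1.0
YM2,2,21.4,5.0
YM2,3,44.1,9.2
YM2,4,61.3,8.4
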