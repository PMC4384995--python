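soil_id,medium,cfu_total_per_g_dry,cfu_clearing_per_g_dry,isolation_rate_percent
CHI,fungal,6.28e4,1.55e4,24.7
TKB,fungal,6.06e4,8.47e3,14.0
HIO,fungal,6.41e4,2.63e3,4.1
MJO,fungal,2.10e5,8.12e4,38.6
TAK,fungal,9.48e4,1.45e4,15.3
KIB,fungal,1.01e5,2.71e4,26.8
OKA,fungal,4.08e4,1.72e4,42.3
AKA,fungal,5.88e4,8.99e3,15.3
MIY,fungal,2.88e4,2.74e3,9.5
YM1,fungal,6.09e4,2.45e4,40.3
YM2,fungal,5.62e4,2.88e3,51.3
CHI,bacterial,4.37e7,2.83e3,0.0
TKB,bacterial,2.59e7,2.49e4,0.1
HIO,bacterial,NA,NA,NA
MJO,bacterial,3.86e7,0.0,0.0
TAK,bacterial,1.82e8,6.13e2,0.0
KIB,bacterial,NA,NA,NA
OKA,bacterial,5.78e7,9.66e3,0.0
AKA,bacterial,NA,NA,NA
MIY,bacterial,NA,NA,NA
YM1,bacterial,2.82e7,2.95e2,0.0
YM2,bacterial,2.53e7,4.64e3,0.0
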