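soil_id,soil_type,soil_texture,ph_h2o,total_c_percent,total_n_percent,region
CHI,alluvial,sandy loam,7.17,1.30,0.13,Chiba
TKB,volcanic ash,loam,6.30,6.22,0.59,Ibaraki
HIO,alluvial,loam,7.05,2.08,0.17,Kagoshima
MJO,volcanic ash,sandy loam,5.36,6.95,0.48,Miyazaki
TAK,alluvial,sandy loam,7.30,NA,NA,Miyazaki
KIB,alluvial,clay loam,6.15,3.37,0.25,Okayama
OKA,alluvial,loam,7.14,4.52,0.39,Okayama
AKA,alluvial,loam,5.78,1.39,0.10,Shimane
MIY,alluvial,sandy loam,5.91,0.97,0.09,Shimane
YM1,volcanic ash,clay loam,7.26,2.61,0.27,Yamanashi
YM2,alluvial,clay loam,7.17,2.07,0.22,Yamanashi
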