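# Synthetic p-nitrophenol calibration series (not measured data).
# A405 of pNP standards in the 330 ul stopped/diluted measurement mixture
# (75 ul supernatant + 200 ul ethanol + 55 ul 2 M Tris), generated from an
# assumed response of 0.05 absorbance units per nmol pNP with small
# instrument noise. Used only as the documented default calibration slope.
nmol_pnp,a405
0.0,0.001
2.0,0.099
5.0,0.251
8.0,0.402
12.0,0.597
16.0,0.803
20.0,0.998
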