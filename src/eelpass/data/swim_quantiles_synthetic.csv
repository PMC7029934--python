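# SYNTHETIC placeholder burst-swimming-speed quantiles — NOT biological data.
# Median ~5 body lengths/s with fixed log-symmetric-ish tail ratios; replace
# with a measured table (e.g. from swimming-performance trials) before use.
length_m,q10,q50,q90,season,temperature_C
0.05,0.150,0.250,0.375,spring,21.8
0.06,0.180,0.300,0.450,spring,21.8
0.07,0.210,0.350,0.525,spring,21.8
0.08,0.240,0.400,0.600,spring,21.8
0.09,0.270,0.450,0.675,spring,21.8
0.10,0.300,0.500,0.750,spring,21.8
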