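# Published relative-energy-difference (RED) values of the twelve
# formulations against beeswax (dimensionless, 2 decimals).
des_name,RED
DES 1,0.81
DES 2,0.85
DES 3,0.65
DES 4,0.91
DES 5,0.92
DES 6,0.95
DES 7,0.74
DES 8,0.71
DES 9,0.80
DES 10,0.83
DES 11,1.35
DES 12,1.40
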