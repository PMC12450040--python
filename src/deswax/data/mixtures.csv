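# The twelve screened eutectic formulations and their molar ratios.
des_name,component1,component2,n1,n2
DES 1,thymol,decanoic acid,1,1
DES 2,menthol,octanoic acid,1,1
DES 3,tetrabutylammonium bromide,octanoic acid,1,1
DES 4,thymol,menthol,1,2
DES 5,betaine,thymol,1,3
DES 6,thymol,menthol,1,1
DES 7,dodecanoic acid,octanoic acid,1,3
DES 8,dodecanoic acid,decanoic acid,1,2
DES 9,menthol,decanoic acid,1,1
DES 10,menthol,dodecanoic acid,3,1
DES 11,choline chloride,tannic acid,20,1
DES 12,choline chloride,diglycolic acid,1,2
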