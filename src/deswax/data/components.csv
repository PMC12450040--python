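# Pure components of the twelve screened eutectic formulations.
# molar_mass in g/mol; density in g/cm^3 (25 C catalog values; betaine,
# choline chloride, tannic and diglycolic acid are crystal densities, the
# only literature numbers available). Group decompositions are declared
# here, not perceived from structure, so they stay reviewable:
#   thymol      = trisubstituted aromatic ring + OH + ring CH3 + isopropyl
#   menthol     = saturated ring (3 CH2 + 3 CH) + ring CH3 + isopropyl + OH
#   TBAB        = 4 n-butyl chains on quaternary N + bromide
#   betaine     = trimethylammonium + CH2 + carboxylate (as ester-type COO)
#   tannic acid = decagalloyl glucose: 10 tetrasubstituted rings, 25 OH,
#                 10 ester links, glucose core (5 CH + CH2 + ring O)
name,molar_mass,density,molar_volume,groups
thymol,150.22,0.965,,C6H3:1;OH:1;CH3:3;CH:1
menthol,156.27,0.890,,CH3:3;CH2:3;CH:4;OH:1;ring:1
tetrabutylammonium bromide,322.37,1.039,,CH3:4;CH2:12;N:1;Br:1
betaine,117.15,1.28,,CH3:3;CH2:1;N:1;COO:1
choline chloride,139.62,1.10,,CH3:3;CH2:2;OH:1;N:1;Cl:1
tannic acid,1701.20,1.59,,C6H2:10;OH:25;COO:10;CH:5;CH2:1;O:1
octanoic acid,144.21,0.910,,CH3:1;CH2:6;COOH:1
decanoic acid,172.26,0.893,,CH3:1;CH2:8;COOH:1
dodecanoic acid,200.32,0.883,,CH3:1;CH2:10;COOH:1
diglycolic acid,134.09,1.43,,CH2:2;COOH:2;O:1
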