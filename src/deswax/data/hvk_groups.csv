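# Hoftyzer-Van Krevelen first-order group contributions.
# F_d, F_p in MPa^0.5 cm^3/mol; E_h in J/mol.
# Aromatic C6H3 (trisubstituted) and C6H2 (tetrasubstituted) extend the
# phenyl -> phenylene step (-160 per extra substitution). Br and the
# quaternary N entry are approximations: the method tabulates no ionic
# groups, so halide counter-ions carry only a dispersive constant.
group,F_d,F_p,E_h
CH3,420,0,0
CH2,270,0,0
CH,80,0,0
C,-70,0,0
CH2=,400,0,0
=CH,200,0,0
=C,70,0,0
C6H5,1430,110,0
C6H4,1270,110,0
C6H3,1110,110,0
C6H2,950,110,0
ring,190,0,0
O,100,400,3000
OH,210,500,20000
COOH,530,420,10000
COO,390,490,7000
CO,290,770,2000
CHO,470,800,4500
NH2,280,0,8400
NH,160,210,3100
N,20,800,5000
CN,430,1100,2500
NO2,500,1070,1500
Cl,450,550,400
Br,550,0,0
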