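# Published Hansen (MPa^0.5) and integer Teas parameters reported for the
# twelve formulations; reference values for regression tests and solute
# calibration.
des_name,delta_d,delta_p,delta_h,F_d,F_p,F_h
DES 1,15.0,2.3,7.8,60,9,31
DES 2,14.6,2.4,8.0,59,9,32
DES 3,17.9,2.7,4.4,72,11,18
DES 4,14.2,2.4,8.4,57,9,34
DES 5,14.2,2.3,8.5,57,9,34
DES 6,13.7,3.1,8.2,55,13,33
DES 7,15.5,2.3,7.2,62,9,29
DES 8,16.0,2.1,7.0,64,8,28
DES 9,15.0,2.2,7.8,60,9,31
DES 10,14.8,2.2,8.0,59,9,32
DES 11,11.4,3.8,9.8,46,15,39
DES 12,11.0,4.8,9.3,44,19,37
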