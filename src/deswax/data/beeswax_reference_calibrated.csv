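# Beeswax solute reference CALIBRATED from the packaged screening
# panel (twelve formulations, reported RED values) by multi-start
# least squares; not a measured Hansen sphere. rms_residual is the
# RMS RED residual of the calibration.
delta_d,delta_p,delta_h,R0,rms_residual
15.796716,0.058585,0.158131,10.053010,0.002381
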