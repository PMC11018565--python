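# s-factor (dimensionless spectrum correction) per anode/filter track
# typical published values; Cu-filtered high-energy spectra lie beyond the
# classic tabulations and carry an extrapolated typical value
anode,filter,s
Mo,Mo,1.000
Mo,Rh,1.017
Rh,Rh,1.061
Rh,Al,1.044
Rh,Ag,1.060
W,Rh,1.042
W,Ag,1.042
W,Al,1.050
Rh,Cu,1.090
W,Cu,1.090
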