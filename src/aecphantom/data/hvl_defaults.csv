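# default HVL model: typical measured HVL (mm Al) per anode/filter vs kVp
# linear interpolation in kVp within each anode/filter track; edges clamp
anode,filter,kvp,hvl_mm_al
Mo,Mo,24,0.31
Mo,Mo,26,0.33
Mo,Mo,28,0.35
Mo,Mo,30,0.37
Mo,Rh,26,0.38
Mo,Rh,28,0.40
Rh,Ag,30,0.48
Rh,Ag,32,0.50
Rh,Ag,34,0.52
Rh,Ag,36,0.54
W,Rh,24,0.47
W,Rh,26,0.49
W,Rh,28,0.52
W,Rh,31,0.55
W,Rh,34,0.57
W,Al,26,0.47
W,Al,30,0.52
W,Al,34,0.57
W,Al,38,0.61
Rh,Cu,45,2.50
Rh,Cu,49,2.80
W,Cu,45,2.80
W,Cu,49,3.10
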