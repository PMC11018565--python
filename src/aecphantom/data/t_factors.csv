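# tomosynthesis per-projection t-factor vs absolute projection angle (deg)
# t(0) = 1 by convention; linear interpolation between nodes
# typical published magnitudes for narrow-angle breast tomosynthesis
angle_deg,t
0.0,1.000
2.5,0.999
5.0,0.997
7.5,0.994
10.0,0.990
12.5,0.985
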