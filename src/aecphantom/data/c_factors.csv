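# c-factor (dimensionless glandularity correction) for PMMA-equivalent breasts
# rows: glandularity (fraction); columns: HVL (mm Al)
# typical published values for the standard PMMA-equivalent breast ladder
glandularity,0.30,0.35,0.40,0.45,0.50,0.55,0.60
0.04,1.299,1.292,1.282,1.275,1.270,1.260,1.249
0.09,1.254,1.245,1.235,1.231,1.225,1.217,1.207
0.20,1.164,1.160,1.151,1.150,1.144,1.139,1.134
0.29,1.109,1.105,1.102,1.099,1.096,1.091,1.088
0.41,1.043,1.041,1.040,1.039,1.037,1.035,1.034
0.67,0.940,0.943,0.945,0.946,0.949,0.952,0.953
0.97,0.889,0.895,0.903,0.908,0.912,0.917,0.921
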