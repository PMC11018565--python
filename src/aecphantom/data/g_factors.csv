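# g-factor (mGy MGD per mGy incident air kerma, 50% glandular breast)
# rows: equivalent breast thickness (mm) of the standard PMMA ladder;
# columns: HVL (mm Al); typical published values of the standard compilation
breast_mm,0.30,0.35,0.40,0.45,0.50,0.55,0.60
21,0.378,0.421,0.460,0.496,0.529,0.559,0.585
32,0.261,0.294,0.326,0.357,0.388,0.419,0.448
45,0.183,0.208,0.232,0.258,0.285,0.311,0.339
53,0.155,0.177,0.198,0.220,0.245,0.272,0.295
60,0.135,0.154,0.172,0.192,0.214,0.236,0.261
75,0.106,0.121,0.136,0.152,0.166,0.189,0.210
90,0.086,0.098,0.111,0.123,0.136,0.154,0.172
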