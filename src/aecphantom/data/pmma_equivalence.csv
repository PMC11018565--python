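# PMMA slab thickness -> equivalent compressed breast (thickness, glandularity)
# standard equivalence ladder; linear interpolation between nodes
pmma_mm,breast_mm,glandularity
20,21,0.97
30,32,0.67
40,45,0.41
45,53,0.29
50,60,0.20
60,75,0.09
70,90,0.04
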