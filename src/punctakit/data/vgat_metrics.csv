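sample,expert,expert_count,algorithm_count,recall,precision,f1
vGAT_X13_Y7,1,23,23,0.83,0.83,0.83
vGAT_X26_Y12,1,126,214,0.87,0.51,0.64
vGAT_X35_Y7,1,110,111,0.76,0.76,0.76
vGAT_X8_Y8,1,78,657,0.92,0.11,0.20
vGAT_X10_Y24,1,39,117,0.82,0.27,0.41
vGAT_X40_Y20,1,197,264,0.70,0.52,0.60
vGAT_X13_Y7,2,47,23,0.51,1.00,0.69
vGAT_X26_Y12,2,363,214,0.47,0.79,0.59
vGAT_X35_Y7,2,178,111,0.45,0.72,0.55
vGAT_X8_Y8,2,285,657,0.74,0.32,0.45
vGAT_X10_Y24,2,140,117,0.49,0.58,0.53
vGAT_X40_Y20,2,234,264,0.67,0.59,0.63
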