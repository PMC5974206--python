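sample,expert,expert_count,algorithm_count,recall,precision,f1
VGlut1_X13_Y7,1,148,143,0.59,0.62,0.61
VGlut1_X26_Y12,1,826,1060,0.60,0.49,0.53
VGlut1_X35_Y7,1,127,225,0.87,0.49,0.63
VGlut1_X8_Y8,1,105,134,0.71,0.55,0.62
VGlut1_X10_Y24,1,21,48,0.61,0.27,0.38
VGlut1_X40_Y20,1,170,145,0.54,0.63,0.58
VGlut1_X13_Y7,2,126,143,0.67,0.59,0.62
VGlut1_X26_Y12,2,1061,1060,0.60,0.60,0.60
VGlut1_X35_Y7,2,241,225,0.64,0.69,0.67
VGlut1_X8_Y8,2,157,134,0.58,0.68,0.63
VGlut1_X10_Y24,2,42,48,0.62,0.54,0.57
VGlut1_X40_Y20,2,123,145,0.67,0.57,0.62
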