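sample,expert1,expert2,algorithm
VGlut1_X13_Y7,148,126,143
VGlut1_X26_Y12,826,1061,1060
VGlut1_X35_Y7,127,241,225
VGlut1_X8_Y8,105,157,134
VGlut1_X10_Y24,21,42,48
VGlut1_X40_Y20,170,123,145
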