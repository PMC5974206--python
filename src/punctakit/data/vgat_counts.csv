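sample,expert1,expert2,algorithm
vGAT_X13_Y7,23,47,23
vGAT_X26_Y12,126,363,214
vGAT_X35_Y7,110,178,111
vGAT_X8_Y8,78,285,657
vGAT_X10_Y24,39,140,117
vGAT_X40_Y20,197,234,264
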