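site,mean_h,sd_h,min_h,max_h
Bone cortical,0.0260,0.0045,0.0195,0.0312
Bone trabecular,0.0039,0.0017,0.0025,0.0064
Brain,0.0047,0.0013,0.0033,0.0069
Heart contents,0.0033,0.0003,0.0030,0.0036
Kidneys,0.0359,0.0104,0.0231,0.0485
Liver,0.0377,0.0055,0.0266,0.0409
Lungs,0.0133,0.0033,0.0105,0.0176
Pancreas,0.0017,0.0004,0.0012,0.0021
Red marrow,0.0099,0.0019,0.0069,0.0127
Salivary gland,0.0005,0.0001,0.0005,0.0006
Spleen,0.0033,0.0004,0.0029,0.0040
Urinary bladder,0.3252,0.0426,0.2662,0.3831
Remainder of body,0.7257,0.0906,0.5861,0.8501
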