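age_band,sex,weight
6-8,M,384225
6-8,F,364181
9-11,M,393951
9-11,F,373399
12-14,M,384886
12-14,F,364807
15-18,M,406019
15-18,F,384838
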