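subject,group,gender,age_yr,weight_kg,height_cm,injected_mbq
1,suspected-infection,F,82,103,152,570.5
2,suspected-infection,F,81,67.1,170,467.7
3,suspected-infection,F,59,106.6,171,710.4
4,suspected-infection,M,61,97.5,179,721.5
5,suspected-infection,M,73,88.9,175,710.4
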