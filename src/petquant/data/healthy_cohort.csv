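subject,group,gender,age_yr,weight_kg,height_cm,injected_mbq
1,healthy,M,27,61.2,183,727.8
2,healthy,M,59,113.4,190,519.8
3,healthy,M,58,111.1,178,572
4,healthy,F,68,93.9,175,506.5
5,healthy,F,71,49,160,550.5
6,healthy,F,26,77.5,160,703
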