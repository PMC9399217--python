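tissue,w_t
gonads,0.20
red-marrow,0.12
colon,0.12
lung,0.12
stomach,0.12
bladder,0.05
breast,0.05
liver,0.05
oesophagus,0.05
thyroid,0.05
skin,0.01
bone-surface,0.01
remainder,0.05
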