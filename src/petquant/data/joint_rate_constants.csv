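subject,region,K1,k2,k3,k4,vt,bp
2,suspected,0.33,0.358,0.225,0.457,1.379,0.493
2,contralateral,0.034,0.076,<0.001,5.122,0.446,<0.001
4,suspected,0.488,1.082,1.234,0.569,1.43,2.169
4,contralateral,0.019,0.053,0.004,6.431,0.374,<0.001
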