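voi_class,peak_suv_max_mean,peak_suv_max_sd
affected-joint,8.5,2.6
contralateral-joint,5.6,1.9
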