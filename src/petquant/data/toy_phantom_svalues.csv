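source,target,s_mGy_per_MBq_h
brain,brain,0.045
brain,lung,0.0006
brain,heart,0.0006
brain,liver,0.0006
brain,kidney,0.0006
brain,bladder,0.0006
brain,remainder,0.0012
lung,brain,0.0006
lung,lung,0.03
lung,heart,0.004
lung,liver,0.002
lung,kidney,0.0006
lung,bladder,0.0006
lung,remainder,0.0012
heart,brain,0.0006
heart,lung,0.004
heart,heart,0.038
heart,liver,0.003
heart,kidney,0.0006
heart,bladder,0.0006
heart,remainder,0.0012
liver,brain,0.0006
liver,lung,0.002
liver,heart,0.003
liver,liver,0.022
liver,kidney,0.0035
liver,bladder,0.0006
liver,remainder,0.0012
kidney,brain,0.0006
kidney,lung,0.0006
kidney,heart,0.0006
kidney,liver,0.0035
kidney,kidney,0.06
kidney,bladder,0.002
kidney,remainder,0.0012
bladder,brain,0.0006
bladder,lung,0.0006
bladder,heart,0.0006
bladder,liver,0.0006
bladder,kidney,0.002
bladder,bladder,0.055
bladder,remainder,0.0012
remainder,brain,0.0012
remainder,lung,0.0012
remainder,heart,0.0012
remainder,liver,0.0012
remainder,kidney,0.0012
remainder,bladder,0.0012
remainder,remainder,0.0025
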