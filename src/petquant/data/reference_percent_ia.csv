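organ,time_min,percent_ia,sd
brain,3,0.88,0.32
brain,10.5,1.99,0.72
brain,21,2.21,0.88
brain,41,2.34,0.96
brain,61,2.33,0.90
brain,81,2.23,0.88
lung,3,5.05,2.29
lung,10.5,3.42,1.77
lung,21,2.46,1.11
lung,41,2.04,1.0
lung,61,1.59,0.63
lung,81,1.73,1.00
heart,3,4.16,1.30
heart,10.5,2.67,0.72
heart,21,2.06,0.54
heart,41,1.72,0.49
heart,61,1.45,0.39
heart,81,1.51,0.57
liver,3,7.41,0.93
liver,10.5,6.95,0.31
liver,21,7.43,0.61
liver,41,8.32,0.92
liver,61,9.41,1.24
liver,81,9.57,0.91
kidney,3,4.46,1.32
kidney,10.5,2.98,0.87
kidney,21,2.29,0.71
kidney,41,1.93,0.51
kidney,61,1.92,0.59
kidney,81,1.69,0.40
bladder,3,0.53,0.39
bladder,10.5,2.47,1.01
bladder,21,4.56,2.08
bladder,41,6.46,2.27
bladder,61,8.00,2.91
bladder,81,7.65,2.22
remainder,3,77.49,5.64
remainder,10.5,78.22,1.54
remainder,21,74.68,1.98
remainder,41,68.47,8.91
remainder,61,66.11,8.37
remainder,81,66.77,9.89
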