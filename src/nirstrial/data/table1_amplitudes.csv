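condition,channel,o2hb_mean_umol_l,o2hb_se_umol_l,hhb_mean_umol_l,hhb_se_umol_l,o2hb_snr
MI-simple,1,0.101,0.013,-0.017,0.002,0.99
MI-simple,2,0.054,0.014,-0.013,0.003,0.54
MI-simple,3,0.038,0.011,-0.011,0.003,1.08
MI-simple,overall,0.064,0.012,-0.014,0.003,0.87
MI-complex,1,0.192,0.012,-0.008,0.006,1.04
MI-complex,2,0.095,0.012,-0.010,0.003,1.23
MI-complex,3,0.065,0.010,-0.007,0.003,1.55
MI-complex,overall,0.118,0.011,-0.009,0.003,1.27
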