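label,rr,rr_sd,tpc,tpc_sd,tfc,tfc_sd,aa_pct,aa_sd,eo_pct,eo_sd
fresh,,,48.51,4.90,42.57,2.95,89.61,4.95,,
50,3.79,0.06,31.18,0.70,26.52,0.46,58.55,0.90,0.82,0.03
60,4.25,0.08,40.72,0.86,28.62,0.61,64.92,0.82,1.23,0.04
70,4.50,0.05,46.42,0.40,36.81,0.82,75.31,1.41,1.93,0.07
80,5.01,0.10,45.19,0.66,35.47,0.71,73.52,0.73,2.01,0.04
90,4.72,0.08,38.52,0.70,31.34,0.78,67.50,0.70,1.73,0.01
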