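label,L,L_sd,a,a_sd,b,b_sd,delta_e,delta_e_sd,chroma,chroma_sd
fresh,42.89,0.86,-10.80,0.73,27.87,0.69,,,29.65,0.83
50,32.75,0.47,-7.18,0.23,21.28,0.09,13.00,0.03,22.46,0.16
60,35.46,0.56,-8.50,0.24,23.35,0.09,11.56,0.04,24.85,0.17
70,39.03,0.47,-9.13,0.17,26.93,0.09,9.96,0.07,28.43,0.14
80,37.77,0.41,-8.72,0.19,25.32,0.09,10.23,0.04,26.78,0.15
90,36.90,0.51,-7.77,0.20,23.12,0.09,10.78,0.01,24.39,0.15
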