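temperature_C,dH_kJ_per_mol,dH_sd,dS_kJ_per_molK,dS_sd,dG_kJ_per_mol,dG_sd
50,23.12,0.014,-0.1077,0.0002,57.90,0.37
60,23.03,0.079,-0.1103,0.0003,59.78,0.25
70,22.93,0.024,-0.1128,0.0004,61.67,0.31
80,22.89,0.030,-0.1152,0.0004,63.55,0.23
90,22.77,0.017,-0.1175,0.0003,65.43,0.47
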