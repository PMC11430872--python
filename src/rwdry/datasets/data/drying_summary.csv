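temperature_C,drying_time_min,drying_time_sd,deff_m2_s,deff_sd,sec_kWh_per_kg,sec_sd,co2_kg_per_kg,co2_sd,nox_kg_per_kg,nox_sd
50,156,4.02,2.48e-8,9.90e-10,5.66,0.14,3.80,0.08,0.023,0.0004
60,124.33,4.25,2.94e-8,1.93e-9,4.91,0.08,3.39,0.04,0.020,0.0004
70,105.00,2.35,3.67e-8,1.75e-9,4.20,0.12,2.91,0.04,0.017,0.0004
80,80.00,2.35,4.87e-8,2.40e-9,3.55,0.11,2.43,0.07,0.014,0.0003
90,56.66,3.60,7.28e-8,2.12e-9,2.81,0.09,1.94,0.03,0.011,0.0003
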