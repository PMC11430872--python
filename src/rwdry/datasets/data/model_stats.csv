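model,temperature_C,r2,mse
logarithmic,50,0.9958,0.0302
logarithmic,60,0.9972,0.0263
logarithmic,70,0.9944,0.0315
logarithmic,80,0.9969,0.0244
logarithmic,90,0.9981,0.0199
page,50,0.9996,0.0124
page,60,0.9990,0.0148
page,70,0.9995,0.0130
page,80,0.9988,0.0169
page,90,0.9984,0.0178
newton,50,0.9696,0.0710
newton,60,0.9858,0.0515
newton,70,0.9803,0.0595
newton,80,0.9900,0.0415
newton,90,0.9729,0.0677
wang_singh,50,0.9965,0.0268
wang_singh,60,0.9908,0.0411
wang_singh,70,0.9952,0.0299
wang_singh,80,0.9798,0.0622
wang_singh,90,0.9868,0.0496
two_term,50,0.9867,0.0488
two_term,60,0.9893,0.0424
two_term,70,0.9811,0.0611
two_term,80,0.9659,0.0722
two_term,90,0.9903,0.0418
henderson_pabis,50,0.9985,0.0173
henderson_pabis,60,0.9968,0.0245
henderson_pabis,70,0.9970,0.0242
henderson_pabis,80,0.9860,0.0512
henderson_pabis,90,0.9862,0.0511
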