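activations,topology,mse,r2,epoch
tansig-tansig-tansig,2-10-10-1,0.000312,0.9975,12
tansig-purelin-tansig,2-10-10-1,1.73e-6,0.9999,147
tansig-purelin,2-10-1,2.45e-6,0.9998,120
tansig-logsig-purelin,2-15-14-1,8.77e-7,0.9999,15
tansig-tansig,2-15-1,0.0041,0.9828,15
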