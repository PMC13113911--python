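id,LTA,HPC,AES,DDP,LAI,OTS
1C3W,6.47,-0.75,1.14,6.16,0.25,0.08
1F88,6.55,-0.63,1.49,8.71,0.35,-0.21
1J4N,6.19,-0.66,1.37,27.46,1.00,0.26
2RH1,6.73,-0.71,1.22,13.52,0.76,0.09
3ODU,6.53,-0.67,1.38,40.33,0.97,-0.23
4DKL,6.35,-0.70,1.32,2.99,-0.16,0.04
2A79,6.63,-0.51,1.46,30.52,-0.29,-0.20
1C17,7.27,-0.90,1.01,0.89,-0.02,-0.05
1OTS,5.45,-0.21,1.70,25.10,0.67,0.13
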