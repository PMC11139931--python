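model_id,FAC2,MB,MGE,NMB,NMGE,RMSE,r,IOA
hargreaves_samani,1.00,0.07,0.13,0.02,0.04,0.17,0.97,0.87
schendel,1.00,0.13,0.15,0.04,0.05,0.18,0.98,0.85
berti,1.00,-0.45,0.45,-0.14,0.14,0.49,0.97,0.54
kharrufa,1.00,0.03,0.45,0.01,0.14,0.51,0.45,0.54
ivanov,0.75,-0.76,0.81,-0.24,0.26,0.99,0.88,0.17
blaney_criddle,1.00,1.02,1.02,0.33,0.33,1.16,0.15,-0.06
papadakis,0.00,-2.02,2.02,-0.65,0.65,2.04,0.89,-0.52
trajkovic,0.08,3.50,3.50,1.12,1.12,3.52,0.95,-0.72
turc,1.00,-0.02,0.06,-0.01,0.02,0.07,1.00,0.94
caprio,1.00,-0.06,0.11,-0.02,0.03,0.12,0.99,0.89
irmak_rs,1.00,0.12,0.14,0.04,0.05,0.16,1.00,0.85
jensen_haise,1.00,0.21,0.21,0.07,0.07,0.23,0.99,0.79
tabari,1.00,-0.25,0.25,-0.08,0.08,0.30,0.99,0.74
jones,1.00,0.30,0.30,0.10,0.10,0.31,0.99,0.69
abtew,1.00,-0.57,0.57,-0.18,0.18,0.57,0.99,0.41
irmak_rn,1.00,0.68,0.68,0.22,0.22,0.72,0.95,0.29
makkink,1.00,1.45,1.45,0.47,0.47,1.47,0.97,-0.34
priestley_taylor,1.00,2.43,2.43,0.78,0.78,2.44,0.96,-0.60
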