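model_id,FAC2,MB,MGE,NMB,NMGE,RMSE,r,IOA
fao_pm,1.00,0.66566,0.66566,0.271218,0.271218,0.689075,0.947607,0.332
berti,1.00,0.22,0.29,0.09,0.12,0.35,0.90,0.71
ivanov,1.00,-0.09,0.52,-0.04,0.21,0.56,0.96,0.47
hargreaves_samani,1.00,0.73,0.73,0.30,0.30,0.77,0.90,0.27
kharrufa,1.00,0.70,0.78,0.28,0.32,0.93,0.18,0.21
schendel,1.00,0.79,0.79,0.32,0.32,0.80,0.97,0.20
papadakis,0.42,-1.36,1.36,-0.55,0.55,1.36,0.97,-0.26
blaney_criddle,0.67,1.69,1.69,0.69,0.69,1.80,-0.12,-0.41
trajkovic,0.00,4.17,4.17,1.70,1.70,4.19,0.85,-0.76
abtew,1.00,0.10,0.12,0.04,0.05,0.16,0.97,0.88
tabari,1.00,0.42,0.42,0.17,0.17,0.48,0.93,0.58
caprio,1.00,0.61,0.61,0.25,0.25,0.66,0.90,0.39
turc,1.00,0.65,0.65,0.26,0.26,0.67,0.95,0.35
irmak_rs,1.00,0.78,0.78,0.32,0.32,0.80,0.96,0.22
jensen_haise,1.00,0.87,0.87,0.36,0.36,0.91,0.91,0.13
jones,1.00,0.97,0.97,0.39,0.39,0.98,0.97,0.03
irmak_rn,1.00,1.35,1.35,0.55,0.55,1.39,0.83,-0.26
makkink,0.67,2.12,2.12,0.86,0.86,2.13,0.98,-0.53
priestley_taylor,0.25,3.10,3.10,1.26,1.26,3.12,0.85,-0.68
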