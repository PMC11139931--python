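model_id,jan,feb,mar,apr,may,jun,jul,aug,sep,oct,nov,dec
pan_observed,2.8,3.1,3.4,3.2,2.7,2.0,1.7,1.8,2.0,2.1,2.2,2.4
fao_pm,3.2,3.6,4.1,4.0,3.7,3.0,2.4,2.5,2.8,2.7,2.6,2.9
hargreaves_samani,3.2,3.5,3.8,3.9,3.8,2.9,2.7,2.8,3.0,2.9,2.7,2.9
schendel,3.5,3.7,4.3,4.0,3.7,2.9,2.6,2.7,2.8,2.8,2.7,3.2
kharrufa,2.6,2.9,3.3,3.8,3.8,3.4,3.2,3.1,3.2,3.0,2.7,2.6
trajkovic,6.5,7.2,7.8,8.1,7.8,6.3,5.9,6.0,6.4,6.1,5.7,5.9
berti,2.7,3.0,3.2,3.3,3.2,2.5,2.3,2.4,2.6,2.4,2.3,2.4
blaney_criddle,3.7,3.9,4.1,4.4,4.5,4.4,4.3,4.1,4.2,4.1,4.0,4.0
papadakis,1.6,1.7,2.0,1.7,1.3,0.6,0.5,0.5,0.6,0.6,0.8,1.3
ivanov,3.4,3.5,4.1,3.5,2.8,1.4,1.1,1.1,1.4,1.4,1.7,2.9
makkink,5.0,5.4,5.8,5.5,5.0,4.4,3.5,3.7,4.1,4.0,4.1,4.4
jensen_haise,3.3,3.8,4.3,4.4,4.1,3.2,2.5,2.7,3.0,2.9,2.8,3.0
irmak_rs,3.4,3.7,4.0,3.9,3.7,3.1,2.6,2.7,3.0,2.9,2.9,3.0
irmak_rn,3.7,4.1,4.4,4.5,4.3,3.9,3.4,3.5,3.7,3.6,3.4,3.4
caprio,3.0,3.4,4.0,4.1,3.8,3.0,2.3,2.4,2.8,2.6,2.5,2.7
jones,3.6,4.0,4.4,4.3,3.9,3.3,2.6,2.7,3.1,3.0,3.0,3.2
turc,3.2,3.5,3.9,3.9,3.6,3.0,2.4,2.6,2.8,2.7,2.7,2.9
tabari,2.9,3.2,3.5,3.5,3.3,2.9,2.3,2.5,2.7,2.6,2.5,2.6
priestley_taylor,5.4,6.1,6.6,6.7,6.3,5.6,4.8,5.0,5.3,5.1,4.8,4.9
abtew,2.8,3.1,3.5,3.4,3.1,2.3,1.8,1.9,2.2,2.1,2.1,2.3
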