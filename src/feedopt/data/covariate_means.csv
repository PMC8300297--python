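covariate,symbol,mean
pre_experimental,x_sy,1.63
weeks_lactating,x_week,18.18
dmi_pasture_forage,x_pf,12.82
dmi_pasture_forage_sq,x_pf2,172.90
dmi_concentrate,x_c,2.26
dmi_concentrate_sq,x_c2,11.49
dmi_pasture_forage_x_concentrate,x_cpf,26.13
pasture_dmd,x_dmd,72.63
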