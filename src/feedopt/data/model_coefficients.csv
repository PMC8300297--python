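term,symbol,coefficient,se
constant,mu,1.465,0.0352
pre_experimental,delta,0.178,0.0790
weeks_lactating,theta,-0.006,0.0024
dmi_pasture_forage,alpha_pf,0.100,0.0189
dmi_pasture_forage_sq,beta_pf,-0.002,0.0007
dmi_concentrate,alpha_c,0.107,0.0168
dmi_concentrate_sq,beta_c,-0.005,0.0011
dmi_pasture_forage_x_concentrate,gamma,-0.002,0.0011
season_spring,tau_spr,0.000,
season_summer,tau_sum,-0.174,
season_autumn,tau_aut,-0.312,
season_winter,tau_win,0.000,
conc_x_season_spring,alpha_c_spr,0.000,
conc_x_season_summer,alpha_c_sum,0.020,
conc_x_season_autumn,alpha_c_aut,0.030,
conc_x_season_winter,alpha_c_win,0.030,
lwt_group_le_500,lambda_i,0.000,
lwt_group_gt_500,lambda_ii,0.116,
pasture_dmd,vartheta,0.014,0.0022
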