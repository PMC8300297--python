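# Gippsland summer demonstration scenario
season: Summer
cow:
  current_yield: 1.69
  weeks_lactating: 19
  liveweight: 500
  pasture_me: 9.93
  current_conc_dmi: 2.0
  current_pasture_dmi: 11.4
  current_forage_dmi: 0.0
prices:
  conc_price_ton: 300
  forage_price_ton: 204
  conc_dm_frac: 0.90
  forage_dm_frac: 0.85
  protein_price: 9.14
  fat_price: 5.02
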