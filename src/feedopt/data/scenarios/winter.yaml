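# Gippsland winter demonstration scenario
season: Winter
cow:
  current_yield: 0.87
  weeks_lactating: 42
  liveweight: 500
  pasture_me: 11.12
  current_conc_dmi: 2.0
  current_pasture_dmi: 8.9
  current_forage_dmi: 0.0
prices:
  conc_price_ton: 314
  forage_price_ton: 217
  conc_dm_frac: 0.90
  forage_dm_frac: 0.85
  protein_price: 9.67
  fat_price: 4.74
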