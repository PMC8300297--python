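# Gippsland autumn demonstration scenario
season: Autumn
cow:
  current_yield: 1.32
  weeks_lactating: 28
  liveweight: 500
  pasture_me: 10.07
  current_conc_dmi: 2.0
  current_pasture_dmi: 11.6
  current_forage_dmi: 0.0
prices:
  conc_price_ton: 294
  forage_price_ton: 182
  conc_dm_frac: 0.90
  forage_dm_frac: 0.85
  protein_price: 9.93
  fat_price: 4.95
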