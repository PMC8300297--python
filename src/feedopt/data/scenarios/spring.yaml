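# Gippsland spring demonstration scenario
season: Spring
cow:
  current_yield: 2.07          # kg milk protein + fat /cow/day
  weeks_lactating: 8
  liveweight: 500              # kg
  pasture_me: 11.94            # MJ/kg DM
  current_conc_dmi: 2.0        # kg DM/cow/day
  current_pasture_dmi: 10.6
  current_forage_dmi: 0.0
prices:
  conc_price_ton: 324          # $/tonne delivered
  forage_price_ton: 251
  conc_dm_frac: 0.90
  forage_dm_frac: 0.85
  protein_price: 7.99          # $/kg milk protein
  fat_price: 4.65              # $/kg milk fat
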