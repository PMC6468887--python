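category,reformulation,portion,sales_weighting,natural_allowance
breakfast_cereals,1,0,1,0
yogurts,1,1,1,1
biscuits,1,1,1,0
cakes,1,1,0,1
morning_goods,1,1,0,1
puddings,1,1,0,0
ice_cream,1,1,0,1
chocolate_confectionery,0,1,0,0
sweet_confectionery,0,1,0,0
sweet_spreads_sauces,1,0,0,0
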