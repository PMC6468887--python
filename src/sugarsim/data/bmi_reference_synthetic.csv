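sex,age_years,cut_minus2sd,cut_plus1sd,cut_plus2sd
male,5,12.90,16.60,18.30
male,6,13.02,16.90,18.71
male,7,13.19,17.34,19.30
male,8,13.39,17.85,19.99
male,9,13.61,18.41,20.76
male,10,13.85,19.03,21.59
male,11,14.11,19.67,22.47
male,12,14.38,20.36,23.40
male,13,14.66,21.07,24.36
male,14,14.95,21.81,25.37
male,15,15.25,22.57,26.41
male,16,15.56,23.36,27.47
male,17,15.87,24.17,28.57
male,18,16.20,25.00,29.70
female,5,12.70,16.90,18.90
female,6,12.82,17.20,19.30
female,7,12.99,17.63,19.87
female,8,13.19,18.13,20.55
female,9,13.41,18.69,21.30
female,10,13.65,19.30,22.11
female,11,13.91,19.94,22.96
female,12,14.18,20.61,23.86
female,13,14.46,21.32,24.80
female,14,14.75,22.05,25.78
female,15,15.05,22.80,26.79
female,16,15.36,23.58,27.83
female,17,15.67,24.38,28.90
female,18,16.00,25.20,30.00
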