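sex,age_class,winter_survival,birth_rate,summer_survival,dispersal_mean_km,dispersal_sd_km,start_count
F,0,0.70,0,0.70,,,72
F,1,0.93,0.07,0.95,2.3,0.4,47
F,2,0.93,0.77,0.95,,,42
F,3-9,0.93,0.90,0.95,,,180
F,10,0.89,0.90,0.92,,,15
F,11,0.84,0.90,0.88,,,12
F,12,0.76,0.90,0.82,,,9
F,13+,0.67,0.90,0.74,,,11
M,0,0.70,,0.70,,,72
M,1,0.88,,0.90,9.3,3.1,45
M,2-9,0.88,,0.90,,,142
M,10,0.82,,0.85,,,5
M,11,0.74,,0.78,,,4
M,12,0.64,,0.69,,,2
M,13+,0.53,,0.58,,,1
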