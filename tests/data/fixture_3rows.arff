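% Tiny synthetic fixture mimicking the UCI Debrecen ARFF dialect
% (3 records; values are hand-written, schema-conforming, not real patients)
@relation debrecen_fixture

@attribute quality {0,1}
@attribute pre_screening {0,1}
@attribute ma_05 numeric
@attribute ma_06 numeric
@attribute ma_07 numeric
@attribute ma_08 numeric
@attribute ma_09 numeric
@attribute ma_10 numeric
@attribute exudate_1 numeric
@attribute exudate_2 numeric
@attribute exudate_3 numeric
@attribute exudate_4 numeric
@attribute exudate_5 numeric
@attribute exudate_6 numeric
@attribute exudate_7 numeric
@attribute exudate_8 numeric
@attribute macula_od_distance numeric
@attribute od_diameter numeric
@attribute am_fm {0,1}
@attribute class {0,1}

@data
1,1,22,22,22,19,18,14,49.895756,17.775994,5.270920,0.771761,0.018632,0.006864,0.003923,0.003923,0.486903,0.100025,1,0
1,1,24,24,22,18,16,13,57.709936,23.799994,3.325423,0.234185,0.003903,0.003903,0.003903,0.003903,0.520908,0.144414,0,0
1,1,62,60,59,54,47,33,55.831441,27.993933,12.687485,4.852282,1.393889,0.373252,0.041817,0.007744,0.530904,0.128548,0,1
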