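period,discharge_m3s,water_level_m,manning,temperature_C
First half of March,1884,970.46,0.1780,13.40
Second half of March,2023.63,969.94,0.1780,13.40
First half of April,1824,970.26,0.1810,16.10
Second half of April,2066.67,970.19,0.1810,16.10
First half of May,1840.67,968.17,0.1704,18.70
Second half of May,2805,957.74,0.1704,18.70
First half of June,3610.67,950.03,0.1071,20.60
Second half of June,5778.67,952.14,0.1071,20.60
First half of July,4654.67,951.51,0.0883,21.10
Second half of July,9596.25,973.66,0.0883,21.10
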