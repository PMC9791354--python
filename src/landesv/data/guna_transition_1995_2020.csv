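# Guna Mountain 1995 -> 2020 land-cover transition areas (ha).
# Rows = 1995 class, columns = 2020 class. Cells are published at 10-ha
# granularity, so marginal totals reproduce published figures to +/-10 ha.
class_name,forest,built-up,grassland,cropland,shrubland
forest,2090,10,0,320,1530
built-up,0,30,30,470,30
grassland,100,110,1260,15010,1940
cropland,240,830,1050,38350,2720
shrubland,1430,60,280,15650,10880
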