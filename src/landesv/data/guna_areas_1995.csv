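# Guna Mountain class areas (ha), 1995 map.
class_name,area_ha
forest,3950
built-up,560
grassland,18430
cropland,43190
shrubland,28300
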