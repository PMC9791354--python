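# Guna Mountain class areas (ha), 2008 map.
class_name,area_ha
forest,2990
built-up,930
grassland,4920
cropland,68410
shrubland,17180
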