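# Guna Mountain class areas (ha), 2020 map.
class_name,area_ha
forest,3860
built-up,1040
grassland,2620
cropland,69810
shrubland,17090
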