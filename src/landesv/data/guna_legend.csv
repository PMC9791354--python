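# Land-cover classes of the Guna Mountain Afroalpine study area and the
# benefit-transfer proxy biome whose coefficients each class uses.
code,class_name,biome_name
1,forest,tropical forest
2,built-up,urban
3,grassland,grass/rangelands
4,cropland,cropland
5,shrubland,tropical forest
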