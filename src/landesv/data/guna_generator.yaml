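# Default synthetic-generator configuration emulating the Guna Mountain
# study system. Proportions are the 1995 class shares; transition_weights
# are the observed 1995->2020 transition areas (ha), row-normalized into
# Markov probabilities at load time; the confusion diagonal of 0.87
# matches the overall-accuracy magnitude reported for maps of this kind;
# band means/spreads are Landsat-like surface reflectances chosen so NDVI
# orders forest > shrubland > grassland > cropland > built-up.
classes:
  - {code: 1, name: forest, biome: tropical forest}
  - {code: 2, name: built-up, biome: urban}
  - {code: 3, name: grassland, biome: grass/rangelands}
  - {code: 4, name: cropland, biome: cropland}
  - {code: 5, name: shrubland, biome: tropical forest}
shape: [200, 200]
pixel_size_m: 30
proportions:
  forest: 0.042
  built-up: 0.006
  grassland: 0.195
  cropland: 0.457
  shrubland: 0.300
transition_weights:
  forest: {forest: 2090, built-up: 10, grassland: 0, cropland: 320, shrubland: 1530}
  built-up: {forest: 0, built-up: 30, grassland: 30, cropland: 470, shrubland: 30}
  grassland: {forest: 100, built-up: 110, grassland: 1260, cropland: 15010, shrubland: 1940}
  cropland: {forest: 240, built-up: 830, grassland: 1050, cropland: 38350, shrubland: 2720}
  shrubland: {forest: 1430, built-up: 60, grassland: 280, cropland: 15650, shrubland: 10880}
confusion:
  forest: {forest: 0.87, built-up: 0.0325, grassland: 0.0325, cropland: 0.0325, shrubland: 0.0325}
  built-up: {forest: 0.0325, built-up: 0.87, grassland: 0.0325, cropland: 0.0325, shrubland: 0.0325}
  grassland: {forest: 0.0325, built-up: 0.0325, grassland: 0.87, cropland: 0.0325, shrubland: 0.0325}
  cropland: {forest: 0.0325, built-up: 0.0325, grassland: 0.0325, cropland: 0.87, shrubland: 0.0325}
  shrubland: {forest: 0.0325, built-up: 0.0325, grassland: 0.0325, cropland: 0.0325, shrubland: 0.87}
bands:
  forest: {green: [0.05, 0.01], red: [0.04, 0.01], nir: [0.45, 0.04], swir: [0.12, 0.02]}
  shrubland: {green: [0.06, 0.01], red: [0.05, 0.01], nir: [0.40, 0.04], swir: [0.15, 0.02]}
  grassland: {green: [0.08, 0.015], red: [0.07, 0.015], nir: [0.35, 0.04], swir: [0.18, 0.03]}
  cropland: {green: [0.09, 0.02], red: [0.09, 0.02], nir: [0.30, 0.05], swir: [0.20, 0.03]}
  built-up: {green: [0.12, 0.02], red: [0.13, 0.02], nir: [0.15, 0.03], swir: [0.25, 0.03]}
smoothing_passes: 0
seed: 0
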