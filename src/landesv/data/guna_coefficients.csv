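# Benefit-transfer value coefficients (USD ha-1 yr-1) for the Guna Mountain
# study system: per-function coefficients over 17 ecosystem-service functions
# in four groups, plus a TOTAL row holding the per-biome totals VC_k.
#
# The published per-function table leaves the biome ownership of several
# cells ambiguous. This file places every printed cell so that each biome
# column sums exactly to its printed total (cropland 225.56, tropical
# forest 986.69, grass/rangelands 293.25, urban 0). Under that constraint
# the tropical-forest and grass/rangelands columns are fully determined by
# printed cells; the cropland column requires exactly one unprinted cell
# of 14.00, assigned here to pollination (RECONSTRUCTED - this equals the
# classic global cropland pollination coefficient). All other cells are
# printed values.
function,group,cropland,tropical forest,grass/rangelands,urban
water supply,provisioning,,8.00,,
food production,provisioning,187.56,32.00,117.45,
raw materials,provisioning,,51.24,,
genetic resources,provisioning,,41.00,,
water regulation,regulating,,6.00,3.00,
climate regulation,regulating,,223.00,,
disturbance regulation,regulating,,5.00,,
gas regulation,regulating,,13.68,7.00,
biological control,regulating,24.00,,23.00,
erosion control,regulating,,245.00,29.00,
waste treatment,regulating,,136.00,87.00,
nutrient cycling,supporting,,184.40,,
pollination,supporting,14.00,7.27,25.00,
soil formation,supporting,,10.00,1.00,
habitat/refuge,supporting,,17.30,,
recreation,cultural,,4.80,0.80,
cultural,cultural,,2.00,,
TOTAL,,225.56,986.69,293.25,0
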