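# Shipped default parameters, produced by the staged anchor calibration
# (scripts/calibrate_defaults.py) against tmesense/data/anchors.csv --
# the in-text characterization values of the biosensor strains.
# Units: rates 1/h, activities and expression in per-hour activity
# units, densities in culture units (carrying capacity ~1), readouts
# in plate-reader A.U.
alpha_P7: 66.16453872780816
background_fluor: 50.0
carrying_capacity: 1.0
detection_threshold: 0.8252728126544576
flip_rate_constant: 0.13914890495701646
fluor_scale: 1.0
growth_rate: 0.11485562384099289
initial_density: 0.1
integrase_degradation: 1.0
lysis_death_coefficient: 3.0
lysis_death_half_max: 0.5700446390076451
lysis_expression_rate: 1.2574231223721737
lysis_max_death_rate: 0.17772107595821934
lysis_protein_decay: 0.3
od_scale_cells: 1.0
od_scale_debris: 0.3924897877121161
pCadC_basal: 0.0
pCadC_coefficient: 1.0
pCadC_direct_gain: 20.67145223171768
pCadC_half_max: 1.0e-06
pCadC_span: 2.0
pLldR_basal: 0.0
pLldR_coefficient: 1.5
pLldR_direct_gain: 20.88820391010909
pLldR_half_max: 2.0
pLldR_span: 2.0
pPepT_basal: 0.0
pPepT_coefficient: 2.0
pPepT_direct_gain: 11.766462144861316
pPepT_half_max: 0.5
pPepT_span: 2.0
reporter_decay: 0.06268675313250445
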