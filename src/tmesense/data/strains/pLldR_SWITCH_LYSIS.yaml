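growth.carrying_capacity: 1.0
growth.growth_rate: 0.11485562384099289
growth.initial_density: 0.1
lysis.death_coefficient: 3.0
lysis.death_half_max: 0.5700446390076451
lysis.lysis_expression_rate: 1.2574231223721737
lysis.lysis_protein_decay: 0.3
lysis.max_death_rate: 0.17772107595821934
measurement.background_fluor: 50.0
measurement.detection_threshold: 0.8252728126544576
measurement.fluor_scale: 1.0
measurement.od_scale_cells: 1.0
measurement.od_scale_debris: 0.3924897877121161
reporter.direct_expression_gain: 20.88820391010909
reporter.reporter_decay: 0.06268675313250445
sensing.channel: lactate
sensing.hill.basal: 0.0
sensing.hill.coefficient: 1.5
sensing.hill.half_max: 2.0
sensing.hill.mode: activating
sensing.hill.span: 2.0
sensing.id: pLldR
strain_id: pLldR_SWITCH_LYSIS
strong.const_activity: 66.16453872780816
switch.flip_rate_constant: 0.13914890495701646
switch.integrase_degradation: 1.0
topology: SWITCH_LYSIS
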