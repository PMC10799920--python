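growth.carrying_capacity: 1.0
growth.growth_rate: 0.11485562384099289
growth.initial_density: 0.1
measurement.background_fluor: 50.0
measurement.detection_threshold: 0.8252728126544576
measurement.fluor_scale: 1.0
measurement.od_scale_cells: 1.0
measurement.od_scale_debris: 0.3924897877121161
reporter.direct_expression_gain: 20.67145223171768
reporter.reporter_decay: 0.06268675313250445
sensing.channel: proton
sensing.hill.basal: 0.0
sensing.hill.coefficient: 1.0
sensing.hill.half_max: 1.0e-06
sensing.hill.mode: activating
sensing.hill.span: 2.0
sensing.id: pCadC
strain_id: pCadC_SWITCH
strong.const_activity: 66.16453872780816
switch.flip_rate_constant: 0.13914890495701646
switch.integrase_degradation: 1.0
topology: SWITCH
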