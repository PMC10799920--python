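growth.carrying_capacity: 1.0
growth.growth_rate: 0.11485562384099289
growth.initial_density: 0.1
measurement.background_fluor: 50.0
measurement.detection_threshold: 0.8252728126544576
measurement.fluor_scale: 1.0
measurement.od_scale_cells: 1.0
measurement.od_scale_debris: 0.3924897877121161
reporter.direct_expression_gain: 11.766462144861316
reporter.reporter_decay: 0.06268675313250445
sensing.channel: oxygen
sensing.hill.basal: 0.0
sensing.hill.coefficient: 2.0
sensing.hill.half_max: 0.5
sensing.hill.mode: repressing
sensing.hill.span: 2.0
sensing.id: pPepT
strain_id: pPepT_DIRECT
strong.const_activity: 66.16453872780816
topology: DIRECT
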