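kind,promoter,topology,channel,signal_value,pH,oxygen_pct,read_time_h,horizon_h,target,units,tolerance,quote
absolute_fluor,pLldR,DIRECT,lactate,10.0,7.3,20.0,48.0,150.0,70.0,A.U.,0.1,reported end-point normalized fluorescence of the lactate sensor without the switch at 10 mM lactate
absolute_fluor,pLldR,SWITCH,lactate,10.0,7.3,20.0,48.0,150.0,120.0,A.U.,0.1,reported end-point normalized fluorescence of the lactate sensor with the amplifying switch at 10 mM lactate
fold_change,pCadC,SWITCH,proton,0.0,5.3,20.0,48.0,150.0,1.9,fold,0.1,reported switch-over-direct amplification of the acid sensor under pH 5.3 induction
fold_change,pPepT,SWITCH,oxygen,0.0,7.3,0.0,48.0,150.0,2.8,fold,0.1,reported switch-over-direct amplification of the hypoxia sensor under anoxia
absolute_fluor,pLldR,SWITCH_LYSIS,lactate,1.0,7.3,20.0,48.0,150.0,25.0,A.U.,0.1,reported dose-response peak of the lactate lysis sensor at 1 mM lactate
absolute_fluor,pLldR,SWITCH_LYSIS,lactate,10.0,7.3,20.0,48.0,150.0,18.0,A.U.,0.1,reported decline of the lactate lysis sensor readout at 10 mM lactate
peak_time,pLldR,SWITCH,lactate,10.0,7.3,20.0,48.0,150.0,20.0,h,0.25,reported time to peak fluorescence after induction (approximate)
persistence_time,pLldR,SWITCH,lactate,10.0,7.3,20.0,48.0,150.0,132.0,h,0.25,reported maximum detectable reaction time of the lactate sensor
persistence_time,pCadC,SWITCH,proton,0.0,5.3,20.0,48.0,150.0,132.0,h,0.25,reported maximum detectable reaction time of the acid sensor
half_activation_signal,pPepT,SWITCH,oxygen,0.5,7.3,20.0,48.0,150.0,0.5,% O2,0.1,reported oxygen level below which the hypoxia promoter triggers
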