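parameter,family,cv
cost.index.EVT_only,gamma,0.15
cost.index.EVT_plus_tPA,gamma,0.15
cost.index.tPA_only,gamma,0.15
cost.index.none,gamma,0.15
cost.mi_hospitalization,gamma,0.15
cost.post_mi_annual,gamma,0.15
cost.acute_recurrent_stroke.scale,gamma,0.15
cost.annual_management.scale,gamma,0.15
utility.mrs0,beta,0.10
utility.mrs1,beta,0.10
utility.mrs2,beta,0.10
utility.mrs3,beta,0.10
utility.mrs4,beta,0.10
utility.mrs5,beta,0.10
utility.event_decrement,beta,0.20
p_fatal_recurrent_stroke,beta,0.10
p_fatal_mi,beta,0.10
hazard.recurrent_stroke.rate,lognormal,0.15
hazard.mi.rate,lognormal,0.15
mortality.scale,lognormal,0.10
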