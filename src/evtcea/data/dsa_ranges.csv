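parameter,low,high
horizon_years,5,40
discount_rate,0.0,0.05
p_fatal_recurrent_stroke,0.15,0.35
cost.acute_recurrent_stroke.scale,0.5,1.5
hazard.recurrent_stroke.rate,0.02,0.06
p_fatal_mi,0.15,0.35
cost.annual_management.scale,0.7,1.3
utility.event_decrement,0.0,0.2
cost.index.EVT_only,26000,40000
mortality.scale,0.8,1.2
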