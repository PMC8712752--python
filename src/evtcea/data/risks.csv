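parameter,value,source,assumed
composite_mi_vascular_5y_risk,0.174,published 5-year risk of MI or vascular death after stroke,false
composite_horizon_years,5,horizon of the published composite risk,false
mi_fraction_of_composite,0.45,assumed split of the composite between MI and vascular death,true
recurrent_stroke_rate_per_year,0.04,assumed default (post-stroke recurrence literature class),true
recurrent_stroke_gompertz_shape,-0.10,assumed alternative (declining recurrence hazard),true
recurrent_stroke_gompertz_baseline,0.050825,assumed alternative matched to 5-year exponential mass,true
p_fatal_recurrent_stroke,0.25,assumed default (recurrent stroke case fatality class),true
p_fatal_mi,0.25,assumed default (MI case fatality class),true
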