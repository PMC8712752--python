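kind,key,value_aud_2018,source,assumed
index_acute,EVT_only,33000,assumed default (Australian EVT costing literature class),true
index_acute,EVT_plus_tPA,35500,assumed default (Australian EVT costing literature class),true
index_acute,tPA_only,16000,assumed default (Australian acute stroke costing literature class),true
index_acute,none,12500,assumed default (Australian acute stroke costing literature class),true
acute_recurrent_stroke,0,11000,assumed default (national administrative cost data class),true
acute_recurrent_stroke,1,12500,assumed default (national administrative cost data class),true
acute_recurrent_stroke,2,14500,assumed default (national administrative cost data class),true
acute_recurrent_stroke,3,18000,assumed default (national administrative cost data class),true
acute_recurrent_stroke,4,22000,assumed default (national administrative cost data class),true
acute_recurrent_stroke,5,26000,assumed default (national administrative cost data class),true
acute_recurrent_stroke,6,10000,assumed default (fatal recurrence; in-hospital death),true
mi_hospitalization,all,8000,assumed default (acute coronary admission cost class),true
annual_management,0,950,assumed default (long-term stroke management cost class),true
annual_management,1,1400,assumed default (long-term stroke management cost class),true
annual_management,2,2000,assumed default (long-term stroke management cost class),true
annual_management,3,3100,assumed default (long-term stroke management cost class),true
annual_management,4,4600,assumed default (long-term stroke management cost class),true
annual_management,5,6400,assumed default (long-term stroke management cost class),true
post_mi_annual,all,1200,assumed default (post-MI secondary prevention cost class),true
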