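key,value,source,assumed
mrs0,0.95,assumed default (mRS utility literature class),true
mrs1,0.93,assumed default (mRS utility literature class),true
mrs2,0.83,assumed default (mRS utility literature class),true
mrs3,0.62,assumed default (mRS utility literature class),true
mrs4,0.42,assumed default (mRS utility literature class),true
mrs5,0.11,assumed default (mRS utility literature class),true
event_decrement,0.10,assumed default (temporary post-event decrement),true
decrement_duration_years,1.0,assumed default (decrement window),true
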