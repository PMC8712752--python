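# Perfusion-imaging eligibility thresholds, editable. Defaults follow the
# published DEFUSE 3 imaging criteria and the DAWN clinical-core mismatch
# groups; core caps are strict comparisons (core < cap; large core = core > 70).
defuse3:
  core_max: 70.0
  mismatch_ratio_min: 1.8
  mismatch_volume_min: 15.0
dawn:
  nihss_floor: 10
  bands:
    - {age_min: 80, age_max: 200, nihss_min: 10, core_max: 21}   # group A
    - {age_min: 0, age_max: 80, nihss_min: 10, core_max: 31}     # group B
    - {age_min: 0, age_max: 80, nihss_min: 20, core_max: 51}     # group C
# late-window definition applied to the registry: onset-to-imaging bounds
time_window:
  min_minutes: 270
  max_minutes: 1440
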