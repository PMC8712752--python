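strategy,qalys,lys,costs,deaths,mi,stroke
evt_defuse3_pos,8.81,12.77,70810,0.626,0.216,0.822
evt_defuse3_neg,6.03,9.19,59302,0.730,0.153,0.594
med_defuse3_pos,7.05,12.09,50347,0.645,0.202,0.779
med_defuse3_neg,7.61,11.60,48767,0.660,0.194,0.747
evt_dawn_pos,7.56,11.30,66096,0.669,0.190,0.728
evt_dawn_neg,5.59,8.45,56788,0.752,0.141,0.544
med_dawn_pos,7.02,11.22,47517,0.671,0.188,0.723
med_dawn_neg,4.64,10.05,43801,0.705,0.168,0.649
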