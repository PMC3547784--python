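cue,lower,upper,category,score
systolic_bp,30,71,,3
systolic_bp,71,81,,2
systolic_bp,81,101,,1
systolic_bp,101,200,,0
systolic_bp,200,300,,2
heart_rate,10,41,,2
heart_rate,41,51,,1
heart_rate,51,101,,0
heart_rate,101,111,,1
heart_rate,111,130,,2
heart_rate,130,300,,3
respiratory_rate,2,9,,2
respiratory_rate,9,15,,0
respiratory_rate,15,21,,1
respiratory_rate,21,30,,2
respiratory_rate,30,80,,3
temperature,25,35,,2
temperature,35,38.5,,0
temperature,38.5,45,,2
consciousness,,,alert,0
consciousness,,,voice,1
consciousness,,,pain,2
consciousness,,,unresponsive,3
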