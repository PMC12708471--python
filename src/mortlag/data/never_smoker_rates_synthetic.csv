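sex,age_start,rate
F,45,1.35e-05
F,50,2.25e-05
F,55,3.6e-05
F,60,5.4e-05
F,65,8.1e-05
F,70,0.000117
F,75,0.000162
F,80,0.000216
F,85,0.00027
M,45,1.5e-05
M,50,2.5e-05
M,55,4e-05
M,60,6e-05
M,65,9e-05
M,70,0.00013
M,75,0.00018
M,80,0.00024
M,85,0.0003
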