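sex,age_start,period_start,period_end,beta
F,45,1950,1969,112.2
F,45,1970,1989,102
F,45,1990,2019,91.8
F,50,1950,1969,102.85
F,50,1970,1989,93.5
F,50,1990,2019,84.15
F,55,1950,1969,93.5
F,55,1970,1989,85
F,55,1990,2019,76.5
F,60,1950,1969,84.15
F,60,1970,1989,76.5
F,60,1990,2019,68.85
F,65,1950,1969,74.8
F,65,1970,1989,68
F,65,1990,2019,61.2
F,70,1950,1969,65.45
F,70,1970,1989,59.5
F,70,1990,2019,53.55
F,75,1950,1969,56.1
F,75,1970,1989,51
F,75,1990,2019,45.9
F,80,1950,1969,46.75
F,80,1970,1989,42.5
F,80,1990,2019,38.25
M,45,1950,1969,132
M,45,1970,1989,120
M,45,1990,2019,108
M,50,1950,1969,121
M,50,1970,1989,110
M,50,1990,2019,99
M,55,1950,1969,110
M,55,1970,1989,100
M,55,1990,2019,90
M,60,1950,1969,99
M,60,1970,1989,90
M,60,1990,2019,81
M,65,1950,1969,88
M,65,1970,1989,80
M,65,1990,2019,72
M,70,1950,1969,77
M,70,1970,1989,70
M,70,1990,2019,63
M,75,1950,1969,66
M,75,1970,1989,60
M,75,1990,2019,54
M,80,1950,1969,55
M,80,1970,1989,50
M,80,1990,2019,45
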