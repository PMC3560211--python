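# Proportion of the population visiting a general practitioner at least once
# in one year, by age band and sex (BEACH general-practice activity data).
# The 75+ band is open-ended.
age_lo,age_hi,sex,attendance
35,44,male,0.73
35,44,female,0.88
45,54,male,0.81
45,54,female,0.89
55,64,male,0.81
55,64,female,0.89
65,74,male,0.93
65,74,female,0.94
75,120,male,0.99
75,120,female,0.99
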