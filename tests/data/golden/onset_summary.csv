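statistic,value
n_with_onset,19.0
median_days,15.0
q1_days,3.0
q3_days,43.5
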