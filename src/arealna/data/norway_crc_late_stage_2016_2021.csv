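age_group,sex,outcome,count,rate_per_10000
total,female,mortality,4652,17.9
total,male,mortality,4726,18.0
total,female,incidence,7737,29.8
total,male,incidence,8300,32.1
lt65,female,mortality,810,3.8
lt65,male,mortality,1009,4.5
lt65,female,incidence,2004,9.4
lt65,male,incidence,2449,10.9
ge65,female,mortality,3842,82.6
ge65,male,mortality,3717,95.3
ge65,female,incidence,5733,123.3
ge65,male,incidence,5851,150.0
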