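age_months,domain,cutoff_logit
24,mean,-7.366
24,cognitive,-4.85
24,language,-7.44
24,gross_motor,-9.95
24,fine_motor,-6.15
24,social,-8.44
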