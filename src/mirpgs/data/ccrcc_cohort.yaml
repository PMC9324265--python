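# Cohort composition of the ccRCC case-control study emulated by the
# synthetic-data generator: 464 clear cell renal cell carcinoma cases and
# 1042 population controls from the Volga-Ural region, with the published
# sex, age and ethnicity breakdown per group.  Age is generated as a
# truncated normal; the published table gives the mean with its standard
# error, so the population SD is a generator parameter (default 10 years).
case:
  n: 464
  male_fraction: 0.608
  age_mean: 56.01
  age_sd: 10.0
  ethnicity:
    Bashkir: 0.168
    Tatar: 0.375
    Russian: 0.457
control:
  n: 1042
  male_fraction: 0.498
  age_mean: 53.6
  age_sd: 10.0
  ethnicity:
    Bashkir: 0.136
    Tatar: 0.439
    Russian: 0.425
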