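variable,pooled_ols,fee,fte,fete,re,iv2sls
expectancy,0.103498,0.315691,0.088595,0.170067,0.161772,0.120627
poverty_threshold,0.056767,0.119627,0.10365,0.044483,0.033923,0.0981
poverty_excluded,0.050569,0.018111,0.048487,0.012039,0.054032,0.016395
poverty_included,0.015629,0.045555,0.023372,0.055605,0.028999,0.052377
emissions,0.000249,0.004559,0.0,0.009023,0.001037,0.021324
exposure,0.192986,0.101863,0.163842,0.065685,0.159116,0.401122
cardio_incidence,0.116289,0.009015,0.108236,0.056032,0.093379,0.001261
ischemic_incidence,3e-06,0.002564,0.000276,0.00014,0.000789,0.003647
copd_incidence,0.003198,7e-06,0.001871,3e-06,4e-06,0.005671
asthma_incidence,0.0,0.01797,0.000483,0.000233,0.034137,0.006785
tracheal_incidence,0.051929,0.055625,0.045616,0.077112,0.077341,0.014908
cardio_death,0.141481,0.00641,0.12903,0.002597,0.053801,0.016227
ischemic_death,0.140486,0.159939,0.12447,0.172176,0.186422,0.00187
copd_death,0.005238,9.2e-05,0.001989,0.000269,5e-05,0.004565
asthma_death,0.001795,0.001808,0.000476,0.001564,1e-06,0.018044
tracheal_death,7.2e-05,0.000545,0.000264,7.3e-05,0.003248,0.003229
real_gdp_pc,0.032866,8.7e-05,0.048509,0.072957,0.036958,4.9e-05
health_expenditures,0.025815,0.014293,0.052561,0.0032,0.008734,0.082605
environmental_taxes,0.009734,0.000703,0.004754,0.026837,0.020746,0.051232
social_contributions,0.030772,0.102449,0.028303,0.137955,0.027745,0.036381
spending,0.000121,0.021325,0.001426,0.0,0.003342,0.00161
corruption,0.020329,0.001757,0.023788,0.089896,0.013509,0.016367
gini,0.000175,4e-06,1e-06,0.002056,0.000916,0.025607
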