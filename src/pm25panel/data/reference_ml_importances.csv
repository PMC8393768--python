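variable,random_forest,extra_trees,adaboost,gradient_boosting,xgboost,lightgbm
expectancy,0.052014,0.098962,0.082059,0.06131,0.075148,0.068
poverty_threshold,0.161033,0.084122,0.212715,0.001461,0.055871,0.05
poverty_excluded,0.004967,0.005565,0.003094,0.003471,0.000797,0.012
poverty_included,0.004442,0.003075,0.003895,0.001881,0.003689,0.056
emissions,0.002551,0.003434,0.000456,0.000959,0.00393,0.036
exposure,0.413803,0.339363,0.45906,0.717532,0.406206,0.16
cardio_incidence,0.007967,0.018523,0.001447,0.003704,0.006088,0.03
ischemic_incidence,0.011549,0.009752,0.001243,0.000447,0.00224,0.022
copd_incidence,0.003862,0.003532,0.000336,0.000258,0.004328,0.028
asthma_incidence,0.022526,0.018407,0.019316,0.008589,0.019928,0.038
tracheal_incidence,0.003572,0.007471,0.000323,0.000678,0.002552,0.032
cardio_death,0.083091,0.110241,0.030849,0.107699,0.139429,0.072
ischemic_death,0.07502,0.114351,0.015745,0.014557,0.041431,0.07
copd_death,0.002787,0.005753,0.002103,0.000533,0.005204,0.054
asthma_death,0.008979,0.008653,0.001088,5.8e-05,0.006329,0.036
tracheal_death,0.002632,0.004054,0.001344,0.000566,0.002391,0.034
real_gdp_pc,0.062514,0.054825,0.128733,0.004961,0.107755,0.032
health_expenditures,0.035335,0.063784,0.022096,0.026985,0.037256,0.026
environmental_taxes,0.002992,0.003486,0.000781,0.002747,0.003695,0.02
social_contributions,0.011451,0.005228,0.001485,0.028149,0.001857,0.044
spending,0.001692,0.002186,0.000382,0.001251,0.00198,0.026
corruption,0.022396,0.032298,0.009096,0.011921,0.071043,0.04
gini,0.002823,0.002935,0.002354,0.000285,0.000853,0.014
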