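variable,pooled_ols,pooled_ols_sig,fee,fee_sig,fte,fte_sig,fete,fete_sig,re,re_sig,iv2sls,iv2sls_sig
expectancy,-0.22805,***,-0.67944,***,-0.223873,***,-0.33379,**,-0.345283,***,0.443984,***
poverty_threshold,0.151001,+,0.25935,**,0.265349,**,0.129913,,0.110895,,0.362384,**
poverty_excluded,-0.111437,***,-0.050287,,-0.122527,***,-0.037093,,-0.115381,***,0.074701,
poverty_included,0.043042,,0.098076,***,0.062356,*,0.108652,***,0.063563,*,-0.192787,***
emissions,-0.006356,,0.019317,,6.5e-05,,0.023919,,-0.011046,,0.078672,**
exposure,0.425233,***,0.219233,***,0.414018,***,0.128386,***,0.339615,***,1.476388,***
cardio_incidence,-0.256236,***,0.064386,,-0.273505,***,-0.143618,,-0.199337,***,-0.031434,
ischemic_incidence,0.001203,,0.009228,,-0.005284,,-0.002822,,0.006475,,0.021552,
copd_incidence,0.014185,,0.001154,,0.012108,,0.000839,,0.001079,,-0.027896,
asthma_incidence,0.000686,,0.063843,,-0.010856,,-0.01207,,0.074828,*,-0.039956,
tracheal_incidence,0.114423,***,0.126039,*,0.115269,***,0.151985,**,0.165075,***,-0.068278,
cardio_death,0.311744,***,0.037946,,0.32605,***,0.024614,,0.119257,*,0.096857,
ischemic_death,0.309552,***,0.344225,***,0.314529,***,0.336414,***,0.397895,***,-0.040304,
copd_death,0.017858,,-0.002824,,0.012587,,-0.003727,,0.00265,,0.025019,
asthma_death,0.012423,,-0.010763,,0.008116,,-0.009243,,-0.000844,,0.066837,**
tracheal_death,0.003558,,0.005269,,0.005872,,-0.002371,,0.011968,,0.020837,
real_gdp_pc,-0.091075,,0.014715,,-0.130006,*,0.172788,+,-0.09853,,0.012191,
health_expenditures,-0.079581,,0.059845,,-0.139424,*,-0.032978,,-0.047508,,-0.304068,***
environmental_taxes,-0.026935,,-0.012153,,-0.020793,,0.056189,*,-0.046456,*,-0.188568,***
social_contributions,-0.067829,***,-0.222701,***,-0.071533,***,-0.269718,***,-0.062536,*,-0.133907,***
spending,-0.006306,,-0.052013,+,0.01636,,0.000347,,-0.020006,,-0.022764,
corruption,-0.045392,**,-0.013054,,-0.084725,,0.175724,***,-0.03102,*,-0.060887,**
gini,0.006347,,-0.002253,,-0.000984,,0.017345,,0.012945,,-0.094555,**
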