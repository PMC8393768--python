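country,economic_index,pm25_mortality
Romania,-1.285505,1.134495
Bulgaria,-1.273869,2.512904
Hungary,-1.029198,0.961135
Lithuania,-1.000805,0.338977
Latvia,-0.998795,0.85705
Poland,-0.987242,1.269684
Croatia,-0.936146,1.080966
Slovakia,-0.825427,1.378815
Estonia,-0.779594,-1.025214
Czechia,-0.692113,0.775506
Portugal,-0.58182,-0.887409
Greece,-0.53301,0.186775
Slovenia,-0.293839,-0.220876
Malta,-0.276277,-0.21284
Spain,-0.031286,-0.894877
Cyprus,0.001373,0.602726
Italy,0.187608,-0.201211
France,0.704757,-0.861699
Germany,0.716147,-0.465943
Belgium,0.784445,-0.330687
Netherlands,0.886835,-0.516262
Austria,0.931414,-0.465291
Finland,0.944055,-1.349146
Ireland,1.006518,-0.965832
Sweden,1.188469,-1.319755
Denmark,1.572643,-0.611526
Luxembourg,2.590962,-0.770464
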