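clearance_16_18: 0.009166666666666667
clearance_other: 0.010104166666666666
colposcopy_compliance: 0.79
colposcopy_sens: 0.95
cycle_length_months: 1
cyto_sens_cancer: 0.65
cyto_sens_precancer: 0.35
cyto_spec: 0.97
hpv_false_pos_16_18_fraction: 0.25
hpv_incidence_16_18:
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 6.422405121320196e-05
- 0.00010933915891340184
- 0.00017493360475681063
- 0.00026303056286999246
- 0.0003716711713555587
- 0.0004934832761173235
- 0.000615522508230315
- 0.0007210080981294275
- 0.0007929139819464858
- 0.0008184658885065699
- 0.0008155859962787781
- 0.0008070078820962334
- 0.0007929139819464858
- 0.0007736009719769843
- 0.0007494691078575033
- 0.0007210080981294275
- 0.0006887802385473485
- 0.0006534016485692185
- 0.000615522508230315
- 0.0005758071932674636
- 0.0005349151528827089
- 0.0004934832761173235
- 0.0004521103602308507
- 0.00041134413986659846
- 0.0003716711713555587
- 0.00033350970356703645
- 0.0002972055149027763
- 0.00026303056286999246
- 0.0002311841833866568
- 0.00020179649453204717
- 0.00017493360475681063
- 0.00015060419775148048
- 0.00012876706297131334
- 0.00010933915891340184
- 9.220383164553203e-05
- 7.721885943577922e-05
- 6.422405121320196e-05
- 5.304818777165377e-05
- 4.351515627958324e-05
- 3.5449187500924406e-05
- 2.8679158544919758e-05
- 2.3041970049719752e-05
- 1.838504428054444e-05
- 1.4568019195404513e-05
- 1.1463733203476156e-05
- 8.958606715858685e-06
- 6.952530647796883e-06
- 5.358369992947143e-06
- 4.101183800797603e-06
- 3.1172527026668283e-06
- 2.3529928207199902e-06
- 1.7638215896176312e-06
- 1.3130276574346844e-06
- 9.706843408396892e-07
- 7.126346096231195e-07
- 5.195655898515561e-07
- 3.761822611081378e-07
- 2.7048339608093385e-07
- 1.9313776461471477e-07
- 1.369550418739429e-07
- 9.6443517239031e-08
- 6.744538117997579e-08
- 4.683985259656964e-08
- 3.2304493813306574e-08
- 2.2125569676401112e-08
- 1.5049084245433165e-08
- 1.0165055863708971e-08
- 6.818573772271463e-09
- 4.542149156794295e-09
- 3.004784387972137e-09
- 1.974009788963116e-09
- 1.2878621169498671e-09
hpv_incidence_other:
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.00014985611949747124
- 0.00025512470413127094
- 0.0004081784110992248
- 0.0006137379800299825
- 0.0008672327331629702
- 0.0011514609776070881
- 0.0014362191858707351
- 0.0016823522289686641
- 0.0018501326245418002
- 0.001909753739848663
- 0.001903033991317149
- 0.001883018391557878
- 0.0018501326245418002
- 0.0018050689346129631
- 0.0017487612516675075
- 0.0016823522289686641
- 0.0016071538899438131
- 0.0015246038466615096
- 0.0014362191858707351
- 0.0013435501176240815
- 0.0012481353567263208
- 0.0011514609776070881
- 0.001054924173871985
- 0.000959802993022063
- 0.0008672327331629702
- 0.000778189308323085
- 0.0006934795347731448
- 0.0006137379800299825
- 0.0005394297612355325
- 0.00047085848724144337
- 0.0004081784110992248
- 0.00035140979475345446
- 0.0003004564802663978
- 0.00025512470413127094
- 0.00021514227383957472
- 0.00018017733868348483
- 0.00014985611949747124
- 0.00012377910480052546
- 0.0001015353646523609
- 8.271477083549028e-05
- 6.691803660481277e-05
- 5.3764596782679415e-05
- 4.2898436654603685e-05
- 3.3992044789277195e-05
- 2.674871080811103e-05
- 2.0903415670336933e-05
- 1.622257151152606e-05
- 1.2502863316876666e-05
- 9.56942886852774e-06
- 7.273589639555933e-06
- 5.4903165816799765e-06
- 4.115583709107806e-06
- 3.0637312006809303e-06
- 2.2649301286259414e-06
- 1.6628140891206122e-06
- 1.2123197096536308e-06
- 8.777586092523215e-07
- 6.311279241888456e-07
- 4.506547841010011e-07
- 3.1956176437253343e-07
- 2.2503487355773897e-07
- 1.5737255608661014e-07
- 1.0929298939199582e-07
- 7.537715223104868e-08
- 5.1626329244935926e-08
- 3.511452990601071e-08
- 2.3718463681987598e-08
- 1.5910005468633412e-08
- 1.0598348032520022e-08
- 7.011163571934986e-09
- 4.606022840913937e-09
- 3.0050116062163564e-09
hpv_sens: 0.92
hpv_spec: 0.91
metadata:
  acquisition_peak_annual: 0.03225182566159235
  dwell_target_years: 20.0
  generator: cervisim.synthetic_params
  lifetime_risk_target: 0.01
  seed: 0
  stylized: true
occult_fraction: 0.0
progression_to_cancer: 0.003645833333333333
progression_to_precancer_16_18: 0.0012499999999999998
progression_to_precancer_other: 0.00031249999999999995
regression_from_precancer_16_18: 0.0067708333333333336
regression_from_precancer_other: 0.0067708333333333336
schema_version: 1
symptomatic_detection_rate: 0.020833333333333332
treatment_compliance: 0.73
vaccine_efficacy_16_18: 0.95
variant_name: long_dwell
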