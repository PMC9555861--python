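clearance_16_18: 0.018333333333333333
clearance_other: 0.02020833333333333
colposcopy_compliance: 0.79
colposcopy_sens: 0.95
cycle_length_months: 1
cyto_sens_cancer: 0.95
cyto_sens_precancer: 0.85
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
- 5.511111673330848e-05
- 9.381368988934379e-05
- 0.0001500684676774444
- 0.00022559135861152101
- 0.0003186776170768013
- 0.0004229861966776882
- 0.0005274218224823324
- 0.0006176369957218486
- 0.0006791044531001544
- 0.0007009413472848447
- 0.0006984803144088225
- 0.0006911495993969008
- 0.0006791044531001544
- 0.0006625973943562236
- 0.00064196920631161
- 0.0006176369957218486
- 0.0005900799218056418
- 0.0005598232982902407
- 0.0005274218224823324
- 0.0004934426878747233
- 0.0004584492951369645
- 0.0004229861966776882
- 0.00038756580091628965
- 0.00035265723380225597
- 0.0003186776170768013
- 0.00028598588479400444
- 0.00025487912997927963
- 0.00022559135861152101
- 0.0001982944331071268
- 0.00017310091500581936
- 0.0001500684676774444
- 0.0001292054541046417
- 0.00011047736039310196
- 9.381368988934379e-05
- 7.911500226842616e-05
- 6.625981293626459e-05
- 5.511111673330848e-05
- 4.5522352523630345e-05
- 3.734267842997463e-05
- 3.0421478341591257e-05
- 2.4612066561224832e-05
- 1.977459739228582e-05
- 1.5778219047968278e-05
- 1.2502536052483304e-05
- 9.838461383249175e-06
- 7.688549497864016e-06
- 5.966904949172846e-06
- 4.598759578011701e-06
- 3.5198054512686205e-06
- 2.6753619556729723e-06
- 2.0194448697608e-06
- 1.5137937875886464e-06
- 1.1269027723970203e-06
- 8.330882002915985e-07
- 6.116178633552849e-07
- 4.459168149728576e-07
- 3.228582906689148e-07
- 2.321423414164414e-07
- 1.6576049606253916e-07
- 1.1754168864896996e-07
- 8.2772674248055e-08
- 5.7885020676717854e-08
- 4.0200321105299254e-08
- 2.7725344986517796e-08
- 1.8989279715331264e-08
- 1.2915883296216179e-08
- 8.724163857998235e-09
- 5.852044115961519e-09
- 3.898301648153079e-09
- 2.578857627444364e-09
- 1.6941948510762472e-09
- 1.1053082782375157e-09
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
- 0.0001285926057110531
- 0.0002188986097418022
- 0.00035015975791403693
- 0.0005263798367602157
- 0.0007435811065125363
- 0.0009869677922479392
- 0.0012306509191254422
- 0.0014411529900176467
- 0.0015845770572336937
- 0.0016355298103313042
- 0.0016297874002872525
- 0.0016126823985927684
- 0.0015845770572336937
- 0.0015460605868311882
- 0.0014979281480604232
- 0.0014411529900176467
- 0.001376853150879831
- 0.0013062543626772283
- 0.0012306509191254422
- 0.0011513662717076876
- 0.0010697150219862504
- 0.0009869677922479392
- 0.0009043202021380091
- 0.0008228668788719306
- 0.0007435811065125363
- 0.000667300397852677
- 0.0005947179699516524
- 0.0005263798367602157
- 0.00046268701058329583
- 0.0004039021350135785
- 0.00035015975791403693
- 0.00030147939291083056
- 0.0002577805075839046
- 0.0002188986097418022
- 0.00018460167195966104
- 0.00015460623018461738
- 0.0001285926057110531
- 0.00010621882255513748
- 8.713291633660747e-05
- 7.098344946371293e-05
- 5.7428155309524606e-05
- 4.614072724866691e-05
- 3.6815844445259316e-05
- 2.917258412246104e-05
- 2.2956409894248075e-05
- 1.793994882834937e-05
- 1.3922778214736642e-05
- 1.0730439015360637e-05
- 8.212879386293448e-06
- 6.242511229903602e-06
- 4.712038029441867e-06
- 3.5321855043735083e-06
- 2.6294398022597142e-06
- 1.943872467347063e-06
- 1.427108347828998e-06
- 1.0404725682700011e-06
- 7.533360115608012e-07
- 5.416654633050299e-07
- 3.8677449081259137e-07
- 2.742639401809299e-07
- 1.9313623991212834e-07
- 1.3506504824567499e-07
- 9.380074924569825e-08
- 6.469247163520819e-08
- 4.430831933577295e-08
- 3.0137061024504415e-08
- 2.0356382335329213e-08
- 1.365476960391021e-08
- 9.096037179023852e-09
- 6.01733446403685e-09
- 3.95312131917791e-09
- 2.5790526492208696e-09
hpv_sens: 0.92
hpv_spec: 0.91
metadata:
  acquisition_peak_annual: 0.027680144866715998
  dwell_target_years: 10.0
  generator: cervisim.synthetic_params
  lifetime_risk_target: 0.01
  seed: 0
  stylized: true
occult_fraction: 0.05
progression_to_cancer: 0.007291666666666666
progression_to_precancer_16_18: 0.0024999999999999996
progression_to_precancer_other: 0.0006249999999999999
regression_from_precancer_16_18: 0.013541666666666667
regression_from_precancer_other: 0.013541666666666667
schema_version: 1
symptomatic_detection_rate: 0.041666666666666664
treatment_compliance: 0.73
vaccine_efficacy_16_18: 0.95
variant_name: short_dwell
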