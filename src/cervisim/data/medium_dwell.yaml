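clearance_16_18: 0.012222222222222221
clearance_other: 0.01347222222222222
colposcopy_compliance: 0.79
colposcopy_sens: 0.95
cycle_length_months: 1
cyto_sens_cancer: 0.8
cyto_sens_precancer: 0.55
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
- 5.9166783607211836e-05
- 0.00010072277283840192
- 0.00016113280041868405
- 0.00024224868656093078
- 0.0003422515961844952
- 0.0004543409503957263
- 0.000566599029189796
- 0.0006635975790679093
- 0.000729700738965966
- 0.000753187229523522
- 0.0007505402146340433
- 0.0007426556197147493
- 0.000729700738965966
- 0.0007119476556078807
- 0.0006897635070279851
- 0.0006635975790679093
- 0.0006339658888586452
- 0.0006014340202487477
- 0.000566599029189796
- 0.0005300712379056827
- 0.0004924566899418892
- 0.0004543409503957263
- 0.00041627481631250073
- 0.00037876236222912364
- 0.0003422515961844952
- 0.0003071278524999998
- 0.00027370990814432614
- 0.00024224868656093078
- 0.0002129283114178926
- 0.00018586919575108718
- 0.00016113280041868405
- 0.0001387276690289707
- 0.00011861634256609132
- 0.00010072277283840192
- 8.493988595501544e-05
- 7.113699127871964e-05
- 5.9166783607211836e-05
- 4.8871742757228275e-05
- 4.0089791686181986e-05
- 3.265912871751597e-05
- 2.6422198885556192e-05
- 2.1228812102536132e-05
- 1.6938450670278547e-05
- 1.3421835139870718e-05
- 1.056183576574332e-05
- 8.25382735761826e-06
- 6.405589120128674e-06
- 4.936849211667482e-06
- 3.778567503187613e-06
- 2.87204062245916e-06
- 2.1679020145382034e-06
- 1.625077472722225e-06
- 1.2097442660286006e-06
- 8.94330282064093e-07
- 6.565789946066935e-07
- 4.786968566872219e-07
- 3.4659205052633977e-07
- 2.4920741580336526e-07
- 1.7794574187490752e-07
- 1.261823059706124e-07
- 8.885737935449001e-08
- 6.214020648043217e-08
- 4.3155485918155985e-08
- 2.9763461661946876e-08
- 2.0385199595018832e-08
- 1.3865341941254882e-08
- 9.36548522068037e-09
- 6.282233300236584e-09
- 4.184869417667158e-09
- 2.7684318171239397e-09
- 1.8187366612743006e-09
- 1.1865604832017595e-09
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
- 0.00013805582841682761
- 0.00023501980328960445
- 0.0003759765343102628
- 0.0005652469353088385
- 0.0007985870577638221
- 0.0010601288842566946
- 0.0013220644014428572
- 0.0015483943511584552
- 0.0017026350575872538
- 0.001757436868888218
- 0.001751260500812768
- 0.0017328631126677485
- 0.0017026350575872538
- 0.0016612111964183884
- 0.0016094481830652985
- 0.0015483943511584552
- 0.0014792537406701721
- 0.0014033460472470782
- 0.0013220644014428572
- 0.0012368328884465928
- 0.001149065609864408
- 0.0010601288842566946
- 0.0009713079047291683
- 0.0008837788452012884
- 0.0007985870577638221
- 0.000716631655833333
- 0.000638656452336761
- 0.0005652469353088385
- 0.0004968327266417494
- 0.00043369479008587003
- 0.0003759765343102628
- 0.00032369789440093164
- 0.0002767714659875464
- 0.00023501980328960445
- 0.00019819306722836937
- 0.00016598631298367914
- 0.00013805582841682761
- 0.00011403406643353264
- 9.354284726775797e-05
- 7.620463367420393e-05
- 6.165179739963112e-05
- 4.953389490591764e-05
- 3.9523051563983275e-05
- 3.131761532636501e-05
- 2.464428345340108e-05
- 1.925893050110927e-05
- 1.4946374613633571e-05
- 1.1519314827224125e-05
- 8.816657507437763e-06
- 6.701428119071373e-06
- 5.058438033922474e-06
- 3.7918474363518583e-06
- 2.8227366207334013e-06
- 2.08677065814955e-06
- 1.5320176540822848e-06
- 1.1169593322701842e-06
- 8.087147845614594e-07
- 5.814839702078522e-07
- 4.1520673104145085e-07
- 2.944253805980956e-07
- 2.0733388516047667e-07
- 1.449938151210084e-07
- 1.0069613380903064e-07
- 6.944807721120937e-08
- 4.7565465721710607e-08
- 3.2352464529594724e-08
- 2.1852798848254196e-08
- 1.4658544367218694e-08
- 9.764695307890036e-09
- 6.459674239955859e-09
- 4.243718876306701e-09
- 2.768641127470772e-09
hpv_sens: 0.92
hpv_spec: 0.91
metadata:
  acquisition_peak_annual: 0.029714937701904396
  dwell_target_years: 15.0
  generator: cervisim.synthetic_params
  lifetime_risk_target: 0.01
  seed: 0
  stylized: true
occult_fraction: 0.0
progression_to_cancer: 0.00486111111111111
progression_to_precancer_16_18: 0.0016666666666666666
progression_to_precancer_other: 0.00041666666666666664
regression_from_precancer_16_18: 0.009027777777777777
regression_from_precancer_other: 0.009027777777777777
schema_version: 1
symptomatic_detection_rate: 0.027777777777777776
treatment_compliance: 0.73
vaccine_efficacy_16_18: 0.95
variant_name: medium_dwell
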