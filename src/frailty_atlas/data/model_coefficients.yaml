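# Fixed-effect coefficient sets of the mixed logistic model of frailty on
# age band (reference 50-54) x gender (reference female) x GDP/capita
# (continuous, thousand EUR), one set per frailty method x missing-data
# approach. These published estimates serve as generator truth for synthetic
# cohorts and as default prediction coefficients.
#
# Provenance notes: two standard errors in the instrument complete-case column
# carry an obvious doubled-decimal typesetting artifact in the source table
# ("0.0.1737", "0.0.1728"); they are read as 0.1737 and 0.1728. One coefficient
# in the index complete-case column is printed with a comma decimal ("1,3843")
# and is read as 1.3843. Point estimates are otherwise unambiguous.
provenance: >
  Transcribed from the published regression table (GDP/capita PPP-adjusted,
  annual average 2000-2004 in thousand EUR); see notes above on typesetting
  artifacts.
sets:
  instrument_mi:
    coefficients:
      intercept: -3.0769
      male: -0.7756
      age_55_59: 0.5233
      age_60_64: 0.7197
      age_65_69: 1.1642
      age_70_74: 1.9076
      age_75_79: 2.4500
      age_80_84: 2.9310
      age_85p: 3.3877
      "age_55_59:male": 0.0879
      "age_60_64:male": 0.2333
      "age_65_69:male": 0.1750
      "age_70_74:male": 0.1192
      "age_75_79:male": 0.0641
      "age_80_84:male": 0.0627
      "age_85p:male": -0.0456
      gdp: -0.0160
      "age_55_59:gdp": -0.0153
      "age_60_64:gdp": -0.0150
      "age_65_69:gdp": -0.0169
      "age_70_74:gdp": -0.0273
      "age_75_79:gdp": -0.0211
      "age_80_84:gdp": -0.0138
      "age_85p:gdp": 0.0048
    se:
      intercept: 0.2629
      male: 0.0906
      age_55_59: 0.1670
      age_60_64: 0.1609
      age_65_69: 0.1571
      age_70_74: 0.1545
      age_75_79: 0.1530
      age_80_84: 0.1544
      age_85p: 0.1575
      "age_55_59:male": 0.1099
      "age_60_64:male": 0.1045
      "age_65_69:male": 0.1017
      "age_70_74:male": 0.1000
      "age_75_79:male": 0.0988
      "age_80_84:male": 0.0993
      "age_85p:male": 0.1005
      gdp: 0.0123
      "age_55_59:gdp": 0.0077
      "age_60_64:gdp": 0.0074
      "age_65_69:gdp": 0.0072
      "age_70_74:gdp": 0.0071
      "age_75_79:gdp": 0.0070
      "age_80_84:gdp": 0.0071
      "age_85p:gdp": 0.0072
  instrument_cc:
    coefficients:
      intercept: -3.1681
      male: -0.7593
      age_55_59: 0.5335
      age_60_64: 0.7104
      age_65_69: 1.0823
      age_70_74: 1.8505
      age_75_79: 2.4107
      age_80_84: 2.9635
      age_85p: 3.5119
      "age_55_59:male": 0.0234
      "age_60_64:male": 0.1464
      "age_65_69:male": 0.0853
      "age_70_74:male": 0.0087
      "age_75_79:male": 0.0249
      "age_80_84:male": -0.0331
      "age_85p:male": -0.1148
      gdp: -0.0195
      "age_55_59:gdp": -0.0175
      "age_60_64:gdp": -0.0158
      "age_65_69:gdp": -0.0152
      "age_70_74:gdp": -0.0264
      "age_75_79:gdp": -0.0220
      "age_80_84:gdp": -0.0170
      "age_85p:gdp": -0.0052
    se:
      intercept: 0.3055
      male: 0.1014
      age_55_59: 0.1868
      age_60_64: 0.1804
      age_65_69: 0.1768
      age_70_74: 0.1737  # printed "0.0.1737"; doubled decimal removed
      age_75_79: 0.1728  # printed "0.0.1728"; doubled decimal removed
      age_80_84: 0.1765
      age_85p: 0.1873
      "age_55_59:male": 0.1243
      "age_60_64:male": 0.1182
      "age_65_69:male": 0.1153
      "age_70_74:male": 0.1135
      "age_75_79:male": 0.1122
      "age_80_84:male": 0.1141
      "age_85p:male": 0.1194
      gdp: 0.0143
      "age_55_59:gdp": 0.0087
      "age_60_64:gdp": 0.0083
      "age_65_69:gdp": 0.0082
      "age_70_74:gdp": 0.0080
      "age_75_79:gdp": 0.0080
      "age_80_84:gdp": 0.0081
      "age_85p:gdp": 0.0085
  index_mi:
    coefficients:
      intercept: -2.5470
      male: -0.4979
      age_55_59: 0.6116
      age_60_64: 0.7450
      age_65_69: 1.2524
      age_70_74: 1.8574
      age_75_79: 2.4623
      age_80_84: 2.8603
      age_85p: 2.9169
      "age_55_59:male": 0.0918
      "age_60_64:male": 0.0741
      "age_65_69:male": -0.0598
      "age_70_74:male": -0.2329
      "age_75_79:male": -0.0607
      "age_80_84:male": -0.2213
      "age_85p:male": 0.0174
      gdp: -0.0200
      "age_55_59:gdp": -0.0172
      "age_60_64:gdp": -0.0131
      "age_65_69:gdp": -0.0189
      "age_70_74:gdp": -0.0212
      "age_75_79:gdp": -0.0190
      "age_80_84:gdp": -0.0078
      "age_85p:gdp": 0.0202
    se:
      intercept: 0.2514
      male: 0.0619
      age_55_59: 0.1106
      age_60_64: 0.1107
      age_65_69: 0.1111
      age_70_74: 0.1112
      age_75_79: 0.1122
      age_80_84: 0.1165
      age_85p: 0.1252
      "age_55_59:male": 0.0728
      "age_60_64:male": 0.0721
      "age_65_69:male": 0.0719
      "age_70_74:male": 0.0719
      "age_75_79:male": 0.0717
      "age_80_84:male": 0.0741
      "age_85p:male": 0.0778
      gdp: 0.0117
      "age_55_59:gdp": 0.0050
      "age_60_64:gdp": 0.0049
      "age_65_69:gdp": 0.0050
      "age_70_74:gdp": 0.0050
      "age_75_79:gdp": 0.0050
      "age_80_84:gdp": 0.0052
      "age_85p:gdp": 0.0056
  index_cc:
    coefficients:
      intercept: -1.9103
      male: -0.5368
      age_55_59: 0.7235
      age_60_64: 1.3843  # printed "1,3843"; comma decimal normalised
      age_65_69: 2.4387
      age_70_74: 2.5534
      age_75_79: 3.3674
      age_80_84: 4.0023
      age_85p: 3.9215
      "age_55_59:male": 0.1620
      "age_60_64:male": -0.0562
      "age_65_69:male": -0.1820
      "age_70_74:male": -0.2660
      "age_75_79:male": -0.1222
      "age_80_84:male": -0.1105
      "age_85p:male": -0.1670
      gdp: -0.0483
      "age_55_59:gdp": -0.0226
      "age_60_64:gdp": -0.0360
      "age_65_69:gdp": -0.0657
      "age_70_74:gdp": -0.0488
      "age_75_79:gdp": -0.0633
      "age_80_84:gdp": -0.0644
      "age_85p:gdp": -0.0402
    se:
      intercept: 0.5348
      male: 0.1055
      age_55_59: 0.3055
      age_60_64: 0.3106
      age_65_69: 0.3106
      age_70_74: 0.3139
      age_75_79: 0.3254
      age_80_84: 0.3757
      age_85p: 0.4798
      "age_55_59:male": 0.1363
      "age_60_64:male": 0.1358
      "age_65_69:male": 0.1351
      "age_70_74:male": 0.1330
      "age_75_79:male": 0.1355
      "age_80_84:male": 0.1458
      "age_85p:male": 0.1777
      gdp: 0.0229
      "age_55_59:gdp": 0.0132
      "age_60_64:gdp": 0.0134
      "age_65_69:gdp": 0.0134
      "age_70_74:gdp": 0.0135
      "age_75_79:gdp": 0.0139
      "age_80_84:gdp": 0.0160
      "age_85p:gdp": 0.0200
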