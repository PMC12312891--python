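date,water_km2,vegetation_km2,mudflat_sand_km2
2013-05-14,1952.7579,1206.6948,134.9064
2013-07-01,2758.9878,408.4092,126.9621
2013-08-02,2461.1868,562.8771,270.2952
2013-10-21,1160.5662,1443.4254,690.3675
2013-12-24,949.7403,1779.3495,565.2693
2014-03-14,1695.4803,1068.1722,530.7066
2014-05-01,1712.1150,1372.7331,209.5110
2014-08-05,2816.0667,397.0215,81.2709
2014-10-08,2600.2413,501.7707,192.3471
2015-02-13,602.5725,1207.3617,1484.4249
2015-09-09,2169.3159,1060.8678,64.1754
2015-10-11,2192.7069,950.7627,150.8895
2015-12-30,2053.2933,636.4899,604.5759
2016-02-16,1447.6608,902.6874,944.0109
2016-03-03,1046.7747,1302.9480,944.6364
2016-06-23,2944.9728,203.2110,146.1753
2016-07-25,3111.9939,138.3570,44.0082
2016-09-27,1202.9751,1357.1982,734.1858
2016-12-16,874.8972,1089.5967,1329.8652
2017-05-09,1784.1996,889.3161,620.8434
2017-07-12,3065.0868,190.6191,38.6532
2017-09-14,2308.8015,607.4694,378.0882
2017-11-01,2234.0142,742.8870,317.4579
2017-12-19,931.3137,1228.6692,1134.3762
2018-03-09,1351.2078,1048.9815,894.1698
2018-04-10,1222.9641,1172.0016,899.3934
2018-07-31,2651.6007,533.7495,109.0089
2018-10-03,1362.6405,1474.3026,457.4160
2019-01-23,1417.3848,1115.4393,761.5350
2019-03-12,2680.6977,204.1254,409.5360
2019-07-18,3079.5804,187.6563,27.1224
2019-08-19,2473.7949,643.9428,176.6214
2019-09-20,1132.6959,1223.7957,937.8675
2020-03-14,1801.0071,887.7033,605.6487
2020-04-15,2035.5876,961.5159,297.2556
2020-08-21,3163.5063,85.5036,45.3492
2020-09-06,3141.4338,98.3178,54.6075
2021-06-05,2969.0469,148.1166,177.1956
2021-08-08,2587.7601,364.8420,341.7570
2021-09-25,2661.0282,472.3110,161.0199
2021-11-12,1012.2894,1481.4981,800.5716
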