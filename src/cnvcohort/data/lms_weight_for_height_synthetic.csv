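# synthetic LMS reference fixture; regenerate with scripts/make_synthetic_lms.py
Sex,Height,L,M,S
1,65,-0.4000,7.3000,0.08000
1,65.5,-0.4000,7.4042,0.08010
1,66,-0.4000,7.5091,0.08020
1,66.5,-0.4000,7.6147,0.08030
1,67,-0.4000,7.7210,0.08040
1,67.5,-0.4000,7.8279,0.08050
1,68,-0.4000,7.9355,0.08060
1,68.5,-0.4000,8.0438,0.08070
1,69,-0.4000,8.1527,0.08080
1,69.5,-0.4000,8.2624,0.08090
1,70,-0.4000,8.3727,0.08100
1,70.5,-0.4000,8.4837,0.08110
1,71,-0.4000,8.5953,0.08120
1,71.5,-0.4000,8.7076,0.08130
1,72,-0.4000,8.8206,0.08140
1,72.5,-0.4000,8.9343,0.08150
1,73,-0.4000,9.0486,0.08160
1,73.5,-0.4000,9.1636,0.08170
1,74,-0.4000,9.2792,0.08180
1,74.5,-0.4000,9.3956,0.08190
1,75,-0.4000,9.5125,0.08200
1,75.5,-0.4000,9.6302,0.08210
1,76,-0.4000,9.7485,0.08220
1,76.5,-0.4000,9.8675,0.08230
1,77,-0.4000,9.9871,0.08240
1,77.5,-0.4000,10.1074,0.08250
1,78,-0.4000,10.2284,0.08260
1,78.5,-0.4000,10.3500,0.08270
1,79,-0.4000,10.4723,0.08280
1,79.5,-0.4000,10.5953,0.08290
1,80,-0.4000,10.7189,0.08300
1,80.5,-0.4000,10.8432,0.08310
1,81,-0.4000,10.9681,0.08320
1,81.5,-0.4000,11.0937,0.08330
1,82,-0.4000,11.2199,0.08340
1,82.5,-0.4000,11.3468,0.08350
1,83,-0.4000,11.4743,0.08360
1,83.5,-0.4000,11.6025,0.08370
1,84,-0.4000,11.7314,0.08380
1,84.5,-0.4000,11.8609,0.08390
1,85,-0.4000,11.9911,0.08400
1,85.5,-0.4000,12.1219,0.08410
1,86,-0.4000,12.2534,0.08420
1,86.5,-0.4000,12.3855,0.08430
1,87,-0.4000,12.5183,0.08440
1,87.5,-0.4000,12.6517,0.08450
1,88,-0.4000,12.7857,0.08460
1,88.5,-0.4000,12.9205,0.08470
1,89,-0.4000,13.0558,0.08480
1,89.5,-0.4000,13.1919,0.08490
1,90,-0.4000,13.3285,0.08500
1,90.5,-0.4000,13.4658,0.08510
1,91,-0.4000,13.6038,0.08520
1,91.5,-0.4000,13.7424,0.08530
1,92,-0.4000,13.8816,0.08540
1,92.5,-0.4000,14.0215,0.08550
1,93,-0.4000,14.1621,0.08560
1,93.5,-0.4000,14.3032,0.08570
1,94,-0.4000,14.4451,0.08580
1,94.5,-0.4000,14.5875,0.08590
1,95,-0.4000,14.7306,0.08600
1,95.5,-0.4000,14.8744,0.08610
1,96,-0.4000,15.0188,0.08620
1,96.5,-0.4000,15.1638,0.08630
1,97,-0.4000,15.3095,0.08640
1,97.5,-0.4000,15.4558,0.08650
1,98,-0.4000,15.6028,0.08660
1,98.5,-0.4000,15.7503,0.08670
1,99,-0.4000,15.8986,0.08680
1,99.5,-0.4000,16.0474,0.08690
1,100,-0.4000,16.1969,0.08700
1,100.5,-0.4000,16.3471,0.08710
1,101,-0.4000,16.4979,0.08720
1,101.5,-0.4000,16.6493,0.08730
1,102,-0.4000,16.8013,0.08740
1,102.5,-0.4000,16.9540,0.08750
1,103,-0.4000,17.1073,0.08760
1,103.5,-0.4000,17.2613,0.08770
1,104,-0.4000,17.4159,0.08780
1,104.5,-0.4000,17.5711,0.08790
1,105,-0.4000,17.7269,0.08800
1,105.5,-0.4000,17.8834,0.08810
1,106,-0.4000,18.0405,0.08820
1,106.5,-0.4000,18.1983,0.08830
1,107,-0.4000,18.3566,0.08840
1,107.5,-0.4000,18.5156,0.08850
1,108,-0.4000,18.6753,0.08860
1,108.5,-0.4000,18.8355,0.08870
1,109,-0.4000,18.9964,0.08880
1,109.5,-0.4000,19.1580,0.08890
1,110,-0.4000,19.3201,0.08900
1,110.5,-0.4000,19.4829,0.08910
1,111,-0.4000,19.6463,0.08920
1,111.5,-0.4000,19.8103,0.08930
1,112,-0.4000,19.9750,0.08940
1,112.5,-0.4000,20.1403,0.08950
1,113,-0.4000,20.3062,0.08960
1,113.5,-0.4000,20.4727,0.08970
1,114,-0.4000,20.6399,0.08980
1,114.5,-0.4000,20.8077,0.08990
1,115,-0.4000,20.9761,0.09000
1,115.5,-0.4000,21.1451,0.09010
1,116,-0.4000,21.3148,0.09020
1,116.5,-0.4000,21.4850,0.09030
1,117,-0.4000,21.6559,0.09040
1,117.5,-0.4000,21.8275,0.09050
1,118,-0.4000,21.9996,0.09060
1,118.5,-0.4000,22.1724,0.09070
1,119,-0.4000,22.3458,0.09080
1,119.5,-0.4000,22.5198,0.09090
1,120,-0.4000,22.6944,0.09100
2,65,-0.4000,7.1000,0.08000
2,65.5,-0.4000,7.2014,0.08010
2,66,-0.4000,7.3034,0.08020
2,66.5,-0.4000,7.4061,0.08030
2,67,-0.4000,7.5094,0.08040
2,67.5,-0.4000,7.6134,0.08050
2,68,-0.4000,7.7181,0.08060
2,68.5,-0.4000,7.8234,0.08070
2,69,-0.4000,7.9294,0.08080
2,69.5,-0.4000,8.0360,0.08090
2,70,-0.4000,8.1433,0.08100
2,70.5,-0.4000,8.2512,0.08110
2,71,-0.4000,8.3598,0.08120
2,71.5,-0.4000,8.4691,0.08130
2,72,-0.4000,8.5789,0.08140
2,72.5,-0.4000,8.6895,0.08150
2,73,-0.4000,8.8007,0.08160
2,73.5,-0.4000,8.9125,0.08170
2,74,-0.4000,9.0250,0.08180
2,74.5,-0.4000,9.1381,0.08190
2,75,-0.4000,9.2519,0.08200
2,75.5,-0.4000,9.3664,0.08210
2,76,-0.4000,9.4814,0.08220
2,76.5,-0.4000,9.5972,0.08230
2,77,-0.4000,9.7135,0.08240
2,77.5,-0.4000,9.8305,0.08250
2,78,-0.4000,9.9482,0.08260
2,78.5,-0.4000,10.0665,0.08270
2,79,-0.4000,10.1854,0.08280
2,79.5,-0.4000,10.3050,0.08290
2,80,-0.4000,10.4252,0.08300
2,80.5,-0.4000,10.5461,0.08310
2,81,-0.4000,10.6676,0.08320
2,81.5,-0.4000,10.7897,0.08330
2,82,-0.4000,10.9125,0.08340
2,82.5,-0.4000,11.0359,0.08350
2,83,-0.4000,11.1600,0.08360
2,83.5,-0.4000,11.2847,0.08370
2,84,-0.4000,11.4100,0.08380
2,84.5,-0.4000,11.5360,0.08390
2,85,-0.4000,11.6626,0.08400
2,85.5,-0.4000,11.7898,0.08410
2,86,-0.4000,11.9177,0.08420
2,86.5,-0.4000,12.0462,0.08430
2,87,-0.4000,12.1753,0.08440
2,87.5,-0.4000,12.3051,0.08450
2,88,-0.4000,12.4355,0.08460
2,88.5,-0.4000,12.5665,0.08470
2,89,-0.4000,12.6981,0.08480
2,89.5,-0.4000,12.8304,0.08490
2,90,-0.4000,12.9634,0.08500
2,90.5,-0.4000,13.0969,0.08510
2,91,-0.4000,13.2311,0.08520
2,91.5,-0.4000,13.3659,0.08530
2,92,-0.4000,13.5013,0.08540
2,92.5,-0.4000,13.6374,0.08550
2,93,-0.4000,13.7741,0.08560
2,93.5,-0.4000,13.9114,0.08570
2,94,-0.4000,14.0493,0.08580
2,94.5,-0.4000,14.1879,0.08590
2,95,-0.4000,14.3271,0.08600
2,95.5,-0.4000,14.4669,0.08610
2,96,-0.4000,14.6073,0.08620
2,96.5,-0.4000,14.7484,0.08630
2,97,-0.4000,14.8901,0.08640
2,97.5,-0.4000,15.0324,0.08650
2,98,-0.4000,15.1753,0.08660
2,98.5,-0.4000,15.3188,0.08670
2,99,-0.4000,15.4630,0.08680
2,99.5,-0.4000,15.6078,0.08690
2,100,-0.4000,15.7532,0.08700
2,100.5,-0.4000,15.8992,0.08710
2,101,-0.4000,16.0459,0.08720
2,101.5,-0.4000,16.1931,0.08730
2,102,-0.4000,16.3410,0.08740
2,102.5,-0.4000,16.4895,0.08750
2,103,-0.4000,16.6386,0.08760
2,103.5,-0.4000,16.7884,0.08770
2,104,-0.4000,16.9387,0.08780
2,104.5,-0.4000,17.0897,0.08790
2,105,-0.4000,17.2413,0.08800
2,105.5,-0.4000,17.3934,0.08810
2,106,-0.4000,17.5463,0.08820
2,106.5,-0.4000,17.6997,0.08830
2,107,-0.4000,17.8537,0.08840
2,107.5,-0.4000,18.0084,0.08850
2,108,-0.4000,18.1636,0.08860
2,108.5,-0.4000,18.3195,0.08870
2,109,-0.4000,18.4760,0.08880
2,109.5,-0.4000,18.6331,0.08890
2,110,-0.4000,18.7908,0.08900
2,110.5,-0.4000,18.9491,0.08910
2,111,-0.4000,19.1080,0.08920
2,111.5,-0.4000,19.2676,0.08930
2,112,-0.4000,19.4277,0.08940
2,112.5,-0.4000,19.5885,0.08950
2,113,-0.4000,19.7498,0.08960
2,113.5,-0.4000,19.9118,0.08970
2,114,-0.4000,20.0744,0.08980
2,114.5,-0.4000,20.2376,0.08990
2,115,-0.4000,20.4014,0.09000
2,115.5,-0.4000,20.5658,0.09010
2,116,-0.4000,20.7308,0.09020
2,116.5,-0.4000,20.8964,0.09030
2,117,-0.4000,21.0626,0.09040
2,117.5,-0.4000,21.2294,0.09050
2,118,-0.4000,21.3969,0.09060
2,118.5,-0.4000,21.5649,0.09070
2,119,-0.4000,21.7335,0.09080
2,119.5,-0.4000,21.9028,0.09090
2,120,-0.4000,22.0726,0.09100
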