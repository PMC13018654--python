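name,x_cm,y_cm,z_cm
F9,-7.0102,4.1652,-4.9952
F7,-7.0263,4.2474,-1.1420
F10,7.2114,4.2067,-5.0452
FT9,-8.4076,1.4567,-5.0429
FT7,-8.0775,1.4120,-1.1135
FC5,-7.7215,1.8643,2.4460
FC3,-6.0182,2.2716,5.5544
FC1,-3.4062,2.6011,7.9987
FCz,0.0376,2.7390,8.8668
FC2,3.4784,2.6438,7.8808
FC4,6.2293,2.3723,5.5630
FC6,7.9534,1.9936,2.4438
FT8,8.1815,1.5417,-1.1330
FT10,8.4113,1.4365,-5.0538
T9,-8.5894,-1.5829,-4.8283
T7,-8.4161,-1.6019,-0.9346
C5,-8.0280,-1.3760,2.9160
C3,-6.5358,-1.1632,6.4358
C1,-3.6158,-0.9984,8.9752
Cz,0.0401,-0.9167,10.0244
C2,3.7672,-0.9624,8.8412
C4,6.7118,-1.0900,6.3580
C6,8.3456,-1.2776,2.9208
T8,8.5080,-1.5020,-0.9490
T10,8.5560,-1.6361,-4.8271
TP9,-8.5619,-4.6515,-4.5707
TP7,-8.4830,-4.6022,-0.7056
CP5,-7.9592,-4.6551,3.0949
CP3,-6.3556,-4.7009,6.5624
CP1,-3.5513,-4.7292,9.1315
CPz,0.0386,-4.7318,9.9432
CP2,3.8384,-4.7073,9.0695
CP4,6.6612,-4.6637,6.5580
CP6,8.3322,-4.6101,3.1206
TP8,8.5549,-4.5545,-0.7130
TP10,8.6162,-4.7035,-4.5869
P9,-7.3009,-7.3766,-4.0998
P7,-7.2434,-7.3453,-0.2487
P5,-6.7272,-7.6291,2.8382
P3,-5.3007,-7.8788,5.5940
P1,-2.8620,-8.0525,7.5436
Pz,0.0325,-8.1115,8.2615
P2,3.1920,-8.0487,7.6716
P4,5.5667,-7.8560,5.6561
P6,6.7888,-7.5904,2.8091
P8,7.3056,-7.3068,-0.2540
P10,7.3895,-7.4390,-4.1220
PO9,-5.4910,-9.8045,-3.5465
PO7,-5.4840,-9.7528,0.2792
PO5,-4.8424,-9.9341,2.1599
PO3,-3.6511,-10.0853,3.7167
PO1,-1.8972,-10.1768,4.6536
POz,0.0216,-10.2178,5.0608
PO2,1.9878,-10.1793,4.6393
PO4,3.6782,-10.0849,3.6397
PO6,4.9820,-9.9446,2.1727
PO8,5.5667,-9.7625,0.2730
PO10,5.4988,-9.8091,-3.5541
O1,-2.9413,-11.2449,0.8839
Oz,0.0108,-11.4892,1.4657
O2,2.9843,-11.2156,0.8800
I1,-2.9818,-11.4570,-2.9216
Iz,0.0004,-11.8565,-2.3078
I2,2.9742,-11.4260,-2.9256
FFT9h,-7.9067,2.8081,-3.1253
FFT7h,-7.4500,3.1300,0.4846
FFC5h,-6.5238,3.6428,3.6144
FFC3h,-4.4410,4.0762,6.1690
FFC4h,4.5853,4.1623,6.0647
FFC6h,6.7128,3.7800,3.5296
FFT8h,7.8053,3.2982,0.4483
FFT10h,8.0097,2.8514,-3.1338
FTT9h,-8.4125,-0.1847,-2.9794
FTT7h,-8.2355,0.0826,0.8579
FCC5h,-7.4692,0.4303,4.5307
FCC3h,-5.1051,0.7177,7.4377
FCC1h,-1.8219,0.9094,9.2529
FCC2h,1.8787,0.9248,9.1562
FCC4h,5.1885,0.7798,7.3507
FCC6h,7.7002,0.5336,4.5350
FTT8h,8.3888,0.1946,0.8501
FTT10h,8.4123,-0.1808,-2.9638
TTP9h,-8.6973,-3.2216,-2.7848
TTP7h,-8.5565,-3.0629,1.1153
CCP5h,-7.6407,-2.9731,4.9217
CCP3h,-5.2928,-2.8906,8.0304
CCP1h,-1.8354,-2.8322,9.8220
CCP2h,2.0220,-2.8148,9.8172
CCP4h,5.5114,-2.8386,8.0474
CCP6h,7.9006,-2.8986,4.9628
TTP8h,8.6000,-2.9820,1.1248
TTP10h,8.8625,-3.2272,-2.8000
TPP9h,-7.8160,-6.0757,-2.3824
TPP7h,-7.6680,-6.0832,1.2880
CPP5h,-6.8115,-6.2975,4.7252
CPP3h,-4.6914,-6.4691,7.5296
CPP1h,-1.5820,-6.5600,9.1164
CPP2h,1.9420,-6.5595,9.2405
CPP4h,5.0674,-6.4482,7.6130
CPP6h,7.1096,-6.2624,4.7328
TPP8h,7.8520,-6.0432,1.2902
TPP10h,7.8903,-6.0955,-2.3805
PPO9h,-6.4597,-8.7656,-1.9014
PPO7h,-6.2959,-8.7503,1.2952
PPO5h,-5.4010,-8.9899,3.7332
PPO3h,-3.5887,-9.1667,5.5504
PPO1h,-1.2047,-9.2607,6.5508
PPO2h,1.3923,-9.2694,6.6958
PPO4h,3.7799,-9.1629,5.6733
PPO6h,5.4609,-8.9640,3.7035
PPO8h,6.3112,-8.7228,1.2856
PPO10h,6.5014,-8.7806,-1.8952
POO9h,-4.2862,-10.8073,-1.3151
POO7h,-4.0120,-10.7129,1.2061
POO5h,-3.1951,-10.8252,2.3047
POO3h,-1.9862,-10.8942,2.9760
POO1h,-0.6919,-10.9260,3.2710
POO2h,0.6804,-10.9163,3.1582
POO4h,2.0294,-10.8914,2.8944
POO6h,3.2176,-10.8252,2.2255
POO8h,4.1098,-10.7245,1.2138
POO10h,4.3895,-10.9127,-1.3170
OI1h,-1.4850,-11.7987,-0.6920
OI2h,1.5095,-11.8018,-0.6933
F9h,-7.1508,4.1119,-3.0854
F10h,7.2798,4.1822,-3.1026
FT9h,-8.2956,1.3320,-3.0808
FT7h,-8.0114,1.6390,0.6850
FC5h,-7.1210,2.0820,4.1324
FC3h,-4.8512,2.4529,6.9136
FC1h,-1.7344,2.7024,8.6923
FC2h,1.8418,2.7271,8.6437
FC4h,4.9548,2.5238,6.8430
FC6h,7.3219,2.2007,4.1297
FT8h,8.1580,1.7684,0.6564
FT10h,8.3371,1.3548,-3.0749
T9h,-8.5132,-1.7056,-2.8731
T7h,-8.2946,-1.4883,1.0009
C5h,-7.5294,-1.2640,4.7904
C3h,-5.1581,-1.0755,7.8035
C1h,-1.8279,-0.9432,9.7356
C2h,1.9678,-0.9304,9.5706
C4h,5.3806,-1.0144,7.7730
C6h,7.8125,-1.1735,4.7840
T8h,8.5137,-1.3906,0.9890
T10h,8.6100,-1.7088,-2.8756
TP9h,-8.4810,-4.7246,-2.6220
TP7h,-8.2704,-4.6298,1.1974
CP5h,-7.3301,-4.6792,4.9109
CP3h,-5.1049,-4.7176,8.0016
CP1h,-1.7354,-4.7342,9.7410
CP2h,2.0680,-4.7232,9.8072
CP4h,5.3997,-4.6890,8.0077
CP6h,7.6550,-4.6373,4.9140
TP8h,8.5200,-4.5807,1.2102
TP10h,8.5443,-4.7221,-2.6176
P9h,-7.2177,-7.4628,-2.1536
P7h,-7.0113,-7.4868,1.2999
P5h,-6.1728,-7.7624,4.3028
P3h,-4.1673,-7.9753,6.6715
P1h,-1.3961,-8.1003,8.1003
P2h,1.7298,-8.0981,8.1641
P4h,4.4748,-7.9611,6.7655
P6h,6.3627,-7.7302,4.3119
P8h,7.2104,-7.4499,1.3025
P10h,7.3282,-7.5077,-2.1576
PO9h,-5.4775,-9.8977,-1.6193
PO7h,-5.1928,-9.8444,1.2304
PO5h,-4.3342,-10.0163,3.0009
PO3h,-2.8007,-10.1361,4.2379
PO1h,-0.9503,-10.2060,4.9418
PO2h,1.0236,-10.2029,4.8942
PO4h,2.8648,-10.1390,4.2138
PO6h,4.4221,-10.0219,2.9808
PO8h,5.2839,-9.8536,1.2250
PO10h,5.5860,-9.9894,-1.6208
O1h,-1.4805,-11.5100,1.1829
O2h,1.5146,-11.5191,1.1833
I1h,-1.5158,-11.8242,-2.6048
I2h,1.5129,-11.8151,-2.6081
FFT9,-7.8484,2.8770,-5.0522
FFT7,-7.6615,2.8653,-1.1508
FFC5,-7.1506,3.3926,2.0993
FFC3,-5.5940,3.8716,4.9788
FFC1,-3.0655,4.2415,7.1040
FFC2,3.2645,4.3101,7.0795
FFC4,5.7504,3.9852,4.8811
FFC6,7.4250,3.5500,2.0380
FFT8,7.9034,3.0344,-1.1997
FFT10,7.9920,2.8942,-5.0914
FTT9,-8.7362,-0.0515,-4.9837
FTT7,-8.2668,-0.0942,-1.0284
FCC5,-8.0133,0.2585,2.7312
FCC3,-6.4161,0.5831,6.0885
FCC1,-3.5749,0.8309,8.5459
FCCz,0.0391,0.9508,9.5560
FCC2,3.6070,0.8652,8.3832
FCC4,6.5164,0.6620,6.0052
FCC6,8.1544,0.3664,2.7201
FTT8,8.3168,0.0182,-1.0364
FTT10,8.5393,-0.0952,-4.9520
TTP9,-8.6632,-3.1238,-4.7178
TTP7,-8.5933,-3.1093,-0.8474
CCP5,-8.1543,-3.0173,3.0273
CCP3,-6.6128,-2.9296,6.5898
CCP1,-3.6930,-2.8570,9.1734
CCPz,0.0396,-2.8163,10.1269
CCP2,3.8540,-2.8225,9.0976
CCP4,6.8854,-2.8640,6.6410
CCP6,8.4553,-2.9378,3.0878
TTP8,8.6000,-3.0280,-0.8435
TTP10,8.6762,-3.1731,-4.7253
TPP9,-8.0715,-6.0646,-4.3594
TPP7,-7.8599,-5.9724,-0.4758
CPP5,-7.3664,-6.1923,3.0380
CPP3,-5.9411,-6.3925,6.2672
CPP1,-3.2728,-6.5320,8.5944
CPPz,0.0366,-6.5750,9.4058
CPP2,3.5892,-6.5138,8.5980
CPP4,6.2256,-6.3615,6.2719
CPP6,7.6671,-6.1548,3.0543
TPP8,7.9319,-5.9303,-0.4840
TPP10,8.1560,-6.1215,-4.3800
PPO9,-6.4570,-8.6432,-3.8324
PPO7,-6.4583,-8.6222,0.0033
PPO5,-5.8712,-8.8705,2.5193
PPO3,-4.6160,-9.0888,4.7446
PPO1,-2.4648,-9.2292,6.2076
PPOz,0.0273,-9.2758,6.7342
PPO2,2.6437,-9.2295,6.3199
PPO4,4.7144,-9.0712,4.7678
PPO6,6.0813,-8.8504,2.5662
PPO8,6.5152,-8.5943,-0.0009
PPO10,6.5038,-8.6718,-3.8448
POO9,-4.3128,-10.7516,-3.2387
POO7,-4.2976,-10.6493,0.5773
POO5,-3.6234,-10.7716,1.7750
POO3,-2.5984,-10.8616,2.6544
POO1,-1.3664,-10.9266,3.2856
POOz,0.0168,-10.9276,3.2790
POO2,1.3651,-10.9106,3.0936
POO4,2.6664,-10.8668,2.6415
POO6,3.7701,-10.7840,1.8069
POO8,4.3670,-10.6599,0.5726
POO10,4.3177,-10.7444,-3.2463
OI1,-2.9391,-11.4511,-1.0020
OIz,0.0052,-11.9343,-0.3936
OI2,2.9553,-11.3636,-1.0051
T3,-8.4161,-1.6019,-0.9346
T5,-7.2434,-7.3453,-0.2487
T4,8.5080,-1.5020,-0.9490
T6,7.3056,-7.3068,-0.2540
M1,-8.6076,-4.4990,-6.7986
M2,8.5794,-4.5009,-6.8031
A1,-8.6076,-2.4990,-6.7986
A2,8.5794,-2.5009,-6.8031
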