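name,x_cm,y_cm,z_cm
Fp1,-2.9437,8.3917,-0.6990
Fpz,0.0112,8.8247,-0.1713
Fp2,2.9872,8.4896,-0.7080
AF9,-4.8971,6.4087,-4.7683
AF7,-5.4840,6.8572,-1.0590
AF5,-4.5431,7.2862,0.5978
AF3,-3.3701,7.6837,2.1227
AF1,-1.8472,7.9904,3.2752
AFz,0.0231,8.0771,3.5417
AF2,1.9820,8.0302,3.2764
AF4,3.5712,7.7726,2.1956
AF6,4.6584,7.3808,0.6034
AF8,5.5743,6.9657,-1.0755
AF10,5.0435,6.3870,-4.8005
F9,-7.0102,4.1652,-4.9952
F7,-7.0263,4.2474,-1.1420
F5,-6.4466,4.8035,1.6921
F3,-5.0244,5.3111,4.2192
F1,-2.7496,5.6931,6.0342
Fz,0.0312,5.8512,6.6462
F2,2.9514,5.7602,5.9540
F4,5.1836,5.4305,4.0814
F6,6.7914,4.9830,1.6367
F8,7.3043,4.4422,-1.2000
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
PPO5h,-5.4010,-8.9899,3.7332
PPO1h,-1.2047,-9.2607,6.5508
PPO2h,1.3923,-9.2694,6.6958
PPO6h,5.4609,-8.9640,3.7035
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
PO3h,-2.8007,-10.1361,4.2379
PO1h,-0.9503,-10.2060,4.9418
PO2h,1.0236,-10.2029,4.8942
PO4h,2.8648,-10.1390,4.2138
O1h,-1.4805,-11.5100,1.1829
O2h,1.5146,-11.5191,1.1833
I1h,-1.5158,-11.8242,-2.6048
I2h,1.5129,-11.8151,-2.6081
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
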