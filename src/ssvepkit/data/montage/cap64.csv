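name,x_cm,y_cm,z_cm
Fp1,-2.9437,8.3917,-0.6990
Fpz,0.0112,8.8247,-0.1713
Fp2,2.9872,8.4896,-0.7080
AF7,-5.4840,6.8572,-1.0590
AF3,-3.3701,7.6837,2.1227
AF4,3.5712,7.7726,2.1956
AF8,5.5743,6.9657,-1.0755
F7,-7.0263,4.2474,-1.1420
F5,-6.4466,4.8035,1.6921
F3,-5.0244,5.3111,4.2192
F1,-2.7496,5.6931,6.0342
Fz,0.0312,5.8512,6.6462
F2,2.9514,5.7602,5.9540
F4,5.1836,5.4305,4.0814
F6,6.7914,4.9830,1.6367
F8,7.3043,4.4422,-1.2000
FT7,-8.0775,1.4120,-1.1135
FC5,-7.7215,1.8643,2.4460
FC3,-6.0182,2.2716,5.5544
FC1,-3.4062,2.6011,7.9987
FCz,0.0376,2.7390,8.8668
FC2,3.4784,2.6438,7.8808
FC4,6.2293,2.3723,5.5630
FC6,7.9534,1.9936,2.4438
FT8,8.1815,1.5417,-1.1330
T7,-8.4161,-1.6019,-0.9346
C5,-8.0280,-1.3760,2.9160
C3,-6.5358,-1.1632,6.4358
C1,-3.6158,-0.9984,8.9752
Cz,0.0401,-0.9167,10.0244
C2,3.7672,-0.9624,8.8412
C4,6.7118,-1.0900,6.3580
C6,8.3456,-1.2776,2.9208
T8,8.5080,-1.5020,-0.9490
TP7,-8.4830,-4.6022,-0.7056
CP5,-7.9592,-4.6551,3.0949
CP3,-6.3556,-4.7009,6.5624
CP1,-3.5513,-4.7292,9.1315
CPz,0.0386,-4.7318,9.9432
CP2,3.8384,-4.7073,9.0695
CP4,6.6612,-4.6637,6.5580
CP6,8.3322,-4.6101,3.1206
TP8,8.5549,-4.5545,-0.7130
P7,-7.2434,-7.3453,-0.2487
P5,-6.7272,-7.6291,2.8382
P3,-5.3007,-7.8788,5.5940
P1,-2.8620,-8.0525,7.5436
Pz,0.0325,-8.1115,8.2615
P2,3.1920,-8.0487,7.6716
P4,5.5667,-7.8560,5.6561
P6,6.7888,-7.5904,2.8091
P8,7.3056,-7.3068,-0.2540
PO7,-5.4840,-9.7528,0.2792
PO5,-4.8424,-9.9341,2.1599
PO3,-3.6511,-10.0853,3.7167
POz,0.0216,-10.2178,5.0608
PO4,3.6782,-10.0849,3.6397
PO6,4.9820,-9.9446,2.1727
PO8,5.5667,-9.7625,0.2730
I1,-2.9818,-11.4570,-2.9216
O1,-2.9413,-11.2449,0.8839
Oz,0.0108,-11.4892,1.4657
O2,2.9843,-11.2156,0.8800
I2,2.9742,-11.4260,-2.9256
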