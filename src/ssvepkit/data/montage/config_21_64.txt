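P7
P5
P3
P1
Pz
P2
P4
P6
P8
PO7
PO5
PO3
POz
PO4
PO6
PO8
O1
Oz
O2
I1
I2
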