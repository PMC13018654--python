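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
P9
P10
PPO5h
PPO6h
PPO1h
PPO2h
POO9h
POO10h
OI1h
OI2h
Iz
OIz
I1h
I2h
O2h
O1h
OI1
OI2
POOz
POO1
POO1h
POO2h
POO2
POO3h
POO4h
POO4
POO3
POO5h
POO6h
POO6
POO5
POO9
POO10
POO8h
POO7h
POO8
POO7
PO1h
PO2h
PO2
PO1
PO4h
PO3h
PO6h
PO5h
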