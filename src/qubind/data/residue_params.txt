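# code sigma_A surface_freq
A 5.039167 0.0740000000
R 6.562778 0.0640000000
N 5.680992 0.0550000000
D 5.580600 0.0700000000
C 5.476460 0.0090000000
Q 6.015920 0.0510000000
E 5.926650 0.0860000000
G 4.509007 0.0760000000
H 6.085475 0.0230000000
I 6.186918 0.0330000000
L 6.186918 0.0520000000
K 6.364707 0.0850000000
M 6.186918 0.0140000000
F 6.364707 0.0260000000
P 5.560083 0.0560000000
S 5.185310 0.0730000000
T 5.621188 0.0620000000
W 6.777398 0.0130000000
Y 6.457635 0.0320000000
V 5.853248 0.0460000000
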