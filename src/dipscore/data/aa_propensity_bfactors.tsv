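aa	score	bfactor_pos_mean	bfactor_pos_sd	bfactor_neg_mean	bfactor_neg_sd
A	558.80	29.14	21.42	30.85	20.20
C	494.90	29.10	23.30	26.61	16.31
D	574.30	32.00	23.58	34.04	20.96
E	494.60	32.62	23.35	35.51	20.95
F	705.30	29.41	22.90	28.15	18.41
G	604.30	32.00	24.25	30.60	20.17
H	615.60	28.38	22.10	30.67	19.56
I	518.30	30.53	22.29	29.01	17.89
K	568.30	32.47	22.93	35.76	21.87
L	570.10	31.11	23.27	29.04	18.19
M	599.60	29.96	22.34	30.20	19.06
N	468.70	31.88	23.42	32.66	20.79
P	601.30	30.60	23.23	32.66	20.87
Q	511.20	32.20	24.31	33.27	20.80
R	566.10	31.83	24.25	33.24	20.55
S	401.40	32.34	23.93	32.13	20.33
T	498.60	31.22	23.47	30.08	19.36
V	535.50	30.19	22.40	28.02	17.71
W	603.10	29.48	22.98	25.18	16.77
Y	541.00	29.73	22.51	26.99	17.72
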