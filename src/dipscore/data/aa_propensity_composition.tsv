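aa	score	comp_pos	comp_neg
A	558.8	7.59	7.21
C	494.9	1.40	1.63
D	574.3	5.41	5.33
E	494.6	5.95	6.49
F	705.3	5.08	4.07
G	604.3	6.66	6.00
H	615.6	2.59	2.26
I	518.3	5.77	6.16
K	568.3	5.80	6.19
L	570.1	10.28	9.77
M	599.6	2.69	2.17
N	468.7	4.01	4.89
P	601.3	5.17	4.70
Q	511.2	3.61	4.10
R	566.1	5.56	5.12
S	401.4	6.21	7.73
T	498.6	5.31	5.63
V	535.5	6.41	6.29
W	603.1	1.47	1.08
Y	541.0	3.04	3.17
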