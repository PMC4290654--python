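aa	score	snep660103	takk010101	karp850101
A	558.8	-0.110	9.8	1.041
C	494.9	-0.184	3.0	0.96
D	574.3	-0.285	4.9	1.033
E	494.6	-0.246	4.4	1.094
F	705.3	0.438	23.0	0.93
G	604.3	-0.073	0.0	1.142
H	615.6	0.320	11.9	0.982
I	518.3	0.001	17.2	1.002
K	568.3	0.049	10.5	1.093
L	570.1	-0.008	17.0	0.967
M	599.6	-0.041	11.9	0.947
N	468.7	-0.136	3.6	1.117
P	601.3	-0.016	15.0	1.055
Q	511.2	-0.067	2.4	1.165
R	566.1	0.079	7.3	1.038
S	401.4	-0.153	2.6	1.169
T	498.6	-0.208	6.9	1.073
V	535.5	-0.155	15.3	0.982
W	603.1	0.493	24.2	0.925
Y	541.0	0.381	17.2	0.961
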