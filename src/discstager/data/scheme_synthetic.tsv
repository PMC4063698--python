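stage_label	nominal_time_h	Ac	Sens	Dac	Ct	N	Wg
A	0	0	0	0	1	1	1
B	5	1	1	1	1	1	2
C	10	2	2	2	2	1	2
D	15	3	3	3	2	2	3
E	20	4	4	3	3	2	3
F	25	5	5	4	3	3	4
G	30	5	5	4	4	3	4
H	35	6	6	5	4	4	5
I	40	6	7	5	5	4	5
J	46	6	7	6	5	5	6
K	49	7	8	6	6	5	6
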