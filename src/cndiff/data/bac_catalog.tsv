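# BAC-platform differential-region catalog (cytolocation, direction class)
label	direction
3q25-q26	A_more
3q28-q29	A_more
4p14-p12	A_more
9q21	A_more
10q11	A_more
11q14	A_more
12p13	A_more
14q12	A_more
16p11	A_more
20p11-20q11	A_more
1p21-p13	B_more
3p26-p25	B_more
3q26	B_more
5q12	B_more
6q21	B_more
8q13	B_more
9q31	B_more
14q32	B_more
15q26	B_more
15q13-q14	B_more
15q24	B_more
17p13	B_more
18p11	B_more
20q13	B_more
22q11	B_more
5p15-p14	both_diff_dir
13q34	both_diff_dir
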