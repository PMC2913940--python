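# Oligo-platform differential-region catalog (cytolocation, direction class)
label	direction
1q31.3	loss_in_A
1q44	loss_in_A
3q26.1	loss_in_A
4q13.2	loss_in_A
5q33.1	loss_in_A
7q35	loss_in_A
11p15.4	loss_in_A
17q21.31	loss_in_A
20p13	loss_in_A
1p36.13	gain_in_A
5p15.33	gain_in_A
5q35.3	gain_in_A
8p11.23	gain_in_A
14q24.3	gain_in_A
14q32.33	gain_in_A
15q11.2	gain_in_A
16p11.2	gain_in_A
17q12	gain_in_A
17q21.32	gain_in_A
17q25.3	gain_in_A
21p11.1	gain_in_A
6p21.32	both_gain_loss_in_A
16q22.3	both_gain_loss_in_A
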