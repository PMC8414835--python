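id,d_max_mm,l_aaa_cm,brachial_dia_mmhg,brachial_sys_mmhg
S1,27,6.6,80,141
S2,29,8.9,86,140
S3,30,6.9,83,122
S4,31,4.1,62,108
S5,33,5.3,82,129
S6,34,8.5,86,139
S7,35,7.7,74,125
S8,37,8.2,87,147
S9,37,7.2,82,133
S10,38,8.8,79,137
M1,44,6.5,80,148
M2,44,6.6,99,179
M3,45,9.5,61,103
M4,45,7.1,78,136
M5,48,8.3,88,136
M6,48,7.9,86,145
M7,49,9.0,96,149
M8,49,6.6,67,122
M9,49,5.3,74,123
M10,49,7.8,83,132
L1,50,5.9,73,138
L2,51,4.5,70,110
L3,51,9.2,91,137
L4,52,6.9,95,147
L5,53,8.9,87,147
L6,53,6.7,94,159
L7,54,8.4,92,142
L8,54,6.7,77,122
L9,55,9.7,81,143
L10,56,5.6,71,107
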