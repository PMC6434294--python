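# Survival times (days) of 44 head-and-neck cancer patients treated with
# combined radiotherapy and chemotherapy (Efron's classic data set).
12.20
23.56
23.74
25.87
31.98
37
41.35
47.38
55.46
58.36
63.47
68.46
78.26
74.47
81.43
84
92
94
110
112
119
127
130
133
140
146
155
159
173
179
194
195
209
249
281
319
339
432
469
519
633
725
817
1776
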