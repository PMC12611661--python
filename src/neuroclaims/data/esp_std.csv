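age_class,weight
0-4,5000
5-9,5500
10-14,5500
15-19,5500
20-24,6000
25-29,6000
30-34,6500
35-39,7000
40-44,7000
45-49,7000
50-54,7000
55-59,6500
60-64,6000
65-69,5500
70-74,5000
75-79,4000
80-84,2500
85-89,1500
90-94,800
95-99,180
100+,20
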