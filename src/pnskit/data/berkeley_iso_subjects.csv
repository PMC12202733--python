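subject_id,site,sex,age_years,height_cm,weight_kg
1,berkeley,M,34,172,73.5
2,berkeley,M,46,177,80
3,berkeley,F,32,175,68
4,berkeley,F,33,160,63
5,berkeley,M,38,178,79
6,berkeley,F,39,172,100
7,berkeley,M,39,172,70
8,berkeley,F,42,172,72
9,berkeley,F,55,165,70
10,berkeley,M,75,185.4,74.8
11,berkeley,F,40,170.18,86.18
12,berkeley,M,37,185,84
13,berkeley,M,68,169,75
14,berkeley,M,68,180.3,97
15,berkeley,F,72,157.48,52.6
16,berkeley,M,30,184,89
17,berkeley,M,41,183,83
18,berkeley,M,48,193,95
19,berkeley,M,32,160,68
20,berkeley,F,72,178,81.65
21,berkeley,F,70,152,52.2
22,berkeley,M,73,178,74.8
23,berkeley,M,80,177,74.84
24,berkeley,F,72,157,51.26
25,berkeley,M,33,160,54
26,berkeley,M,68,,
27,berkeley,F,43,165,54.43
28,berkeley,M,60,172,90.71
29,berkeley,M,74,176,58
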