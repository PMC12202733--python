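subject_id,site,sex,age_years,height_cm,weight_kg
1,erlangen,M,74,172,73
2,erlangen,M,68,178,93
3,erlangen,F,57,168,95
4,erlangen,M,57,187,93
5,erlangen,M,67,172,93
6,erlangen,F,64,164,68
7,erlangen,M,67,180,90
8,erlangen,M,51,183,72
9,erlangen,F,52,164,74
10,erlangen,M,61,186,90
11,erlangen,F,71,170,64
12,erlangen,F,47,168,52
13,erlangen,F,21,154,54
14,erlangen,M,31,188,87
15,erlangen,M,58,183,92
16,erlangen,F,52,175,85
17,erlangen,F,67,157,63
18,erlangen,F,73,169,68
19,erlangen,F,24,168,65
20,erlangen,F,48,168,69
21,erlangen,F,62,160,65
22,erlangen,F,51,170,82
23,erlangen,M,65,180,80
24,erlangen,F,53,169,70
25,erlangen,M,68,186,82
26,erlangen,F,70,168,74
27,erlangen,M,73,191,83
28,erlangen,F,59,162,87
29,erlangen,M,73,174,73
30,erlangen,M,67,183,89
31,erlangen,M,65,183,73
32,erlangen,F,49,167,53
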