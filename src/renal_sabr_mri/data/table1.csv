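patient_id,timepoint,AP_mm,TR_mm,CC_mm
1,baseline,43,49,72
1,m6,51,60,60
1,m12,51,35,48
1,m24,24,22,29
1,last,24,22,29
2,baseline,31,38,37
2,m6,27,34,31
2,m12,30,26,29
2,m24,20,16,21
2,last,17,17,18
3,baseline,38,61,56
3,m6,-,-,-
3,m12,27,43,44
3,m24,28,39,39
3,last,28,39,39
4,baseline,30,21,41
4,m6,28,20,33
4,m12,26,16,26
4,m24,24,14,26
4,last,24,14,26
5,baseline,41,30,37
5,m6,-,-,-
5,m12,29,21,30
5,m24,26,16,35
5,last,39,19,30
6,baseline,30,34,34
6,m6,32,37,42
6,m12,27,33,30
6,m24,27,29,30
6,last,26,30,29
7,baseline,64,67,67
7,m6,61,70,76
7,m12,58,66,77
7,m24,63,67,76
7,last,64,68,75
8,baseline,19,28,36
8,m6,29,25,33
8,m12,22,28,31
8,m24,24,32,31
8,last,24,32,31
9,baseline,53,45,53
9,m6,57,47,53
9,m12,57,51,57
9,m24,-,-,-
9,last,58,48,59
10,baseline,29,35,31
10,m6,35,44,39
10,m12,31,35,40
10,m24,-,-,-
10,last,31,35,40
11,baseline,34,58,56
11,m6,37,61,63
11,m12,36,60,64
11,m24,42,61,61
11,last,42,61,61
12,baseline,23,22,21
12,m6,24,19,24
12,m12,23,21,23
12,m24,29,27,25
12,last,28,28,26
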