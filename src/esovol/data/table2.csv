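patient,method,observer,phase,volume_ml
1,manual,resident,arterial,15
1,manual,resident,venous,14
1,manual,consultant,arterial,5
1,manual,consultant,venous,5
1,semiauto,resident,arterial,33
1,semiauto,resident,venous,31
1,semiauto,consultant,arterial,3
1,semiauto,consultant,venous,3
2,manual,resident,arterial,42
2,manual,resident,venous,44
2,manual,consultant,arterial,13
2,manual,consultant,venous,8
2,semiauto,resident,arterial,36
2,semiauto,resident,venous,31
2,semiauto,consultant,arterial,24
2,semiauto,consultant,venous,28
3,manual,resident,arterial,36
3,manual,resident,venous,44
3,manual,consultant,arterial,5
3,manual,consultant,venous,6
3,semiauto,resident,arterial,23
3,semiauto,resident,venous,26
3,semiauto,consultant,arterial,25
3,semiauto,consultant,venous,25
4,manual,resident,arterial,44
4,manual,resident,venous,50
4,manual,consultant,arterial,16
4,manual,consultant,venous,15
4,semiauto,resident,arterial,28
4,semiauto,resident,venous,21
4,semiauto,consultant,arterial,26
4,semiauto,consultant,venous,25
5,manual,resident,arterial,57
5,manual,resident,venous,52
5,manual,consultant,arterial,30
5,manual,consultant,venous,33
5,semiauto,resident,arterial,48
5,semiauto,resident,venous,59
5,semiauto,consultant,arterial,29
5,semiauto,consultant,venous,35
6,manual,resident,arterial,46
6,manual,resident,venous,54
6,manual,consultant,arterial,43
6,manual,consultant,venous,31
6,semiauto,resident,arterial,39
6,semiauto,resident,venous,33
6,semiauto,consultant,arterial,33
6,semiauto,consultant,venous,36
7,manual,resident,arterial,105
7,manual,resident,venous,99
7,manual,consultant,arterial,62
7,manual,consultant,venous,63
7,semiauto,resident,arterial,70
7,semiauto,resident,venous,83
7,semiauto,consultant,arterial,68
7,semiauto,consultant,venous,74
8,manual,resident,arterial,135
8,manual,resident,venous,125
8,manual,consultant,arterial,81
8,manual,consultant,venous,70
8,semiauto,resident,arterial,95
8,semiauto,resident,venous,101
8,semiauto,consultant,arterial,69
8,semiauto,consultant,venous,68
9,manual,resident,arterial,51
9,manual,resident,venous,66
9,manual,consultant,arterial,21
9,manual,consultant,venous,23
9,semiauto,resident,arterial,34
9,semiauto,resident,venous,42
9,semiauto,consultant,arterial,19
9,semiauto,consultant,venous,26
10,manual,resident,arterial,65
10,manual,resident,venous,56
10,manual,consultant,arterial,23
10,manual,consultant,venous,35
10,semiauto,resident,arterial,47
10,semiauto,resident,venous,40
10,semiauto,consultant,arterial,41
10,semiauto,consultant,venous,40
11,manual,resident,arterial,137
11,manual,resident,venous,132
11,manual,consultant,arterial,73
11,manual,consultant,venous,78
11,semiauto,resident,arterial,111
11,semiauto,resident,venous,110
11,semiauto,consultant,arterial,92
11,semiauto,consultant,venous,104
12,manual,resident,arterial,73
12,manual,resident,venous,81
12,manual,consultant,arterial,58
12,manual,consultant,venous,59
12,semiauto,resident,arterial,59
12,semiauto,resident,venous,62
12,semiauto,consultant,arterial,59
12,semiauto,consultant,venous,54
13,manual,resident,arterial,66
13,manual,resident,venous,69
13,manual,consultant,arterial,45
13,manual,consultant,venous,48
13,semiauto,resident,arterial,50
13,semiauto,resident,venous,50
13,semiauto,consultant,arterial,40
13,semiauto,consultant,venous,38
14,manual,resident,arterial,27
14,manual,resident,venous,35
14,manual,consultant,arterial,17
14,manual,consultant,venous,17
14,semiauto,resident,arterial,19
14,semiauto,resident,venous,22
14,semiauto,consultant,arterial,17
14,semiauto,consultant,venous,16
15,manual,resident,arterial,49
15,manual,resident,venous,64
15,manual,consultant,arterial,36
15,manual,consultant,venous,36
15,semiauto,resident,arterial,47
15,semiauto,resident,venous,55
15,semiauto,consultant,arterial,28
15,semiauto,consultant,venous,31
16,manual,resident,arterial,32
16,manual,resident,venous,30
16,manual,consultant,arterial,24
16,manual,consultant,venous,24
16,semiauto,resident,arterial,18
16,semiauto,resident,venous,24
16,semiauto,consultant,arterial,20
16,semiauto,consultant,venous,25
17,manual,resident,arterial,56
17,manual,resident,venous,46
17,manual,consultant,arterial,35
17,manual,consultant,venous,32
17,semiauto,resident,arterial,44
17,semiauto,resident,venous,34
17,semiauto,consultant,arterial,38
17,semiauto,consultant,venous,38
18,manual,resident,arterial,59
18,manual,resident,venous,44
18,manual,consultant,arterial,36
18,manual,consultant,venous,32
18,semiauto,resident,arterial,77
18,semiauto,resident,venous,77
18,semiauto,consultant,arterial,80
18,semiauto,consultant,venous,75
19,manual,resident,arterial,51
19,manual,resident,venous,57
19,manual,consultant,arterial,42
19,manual,consultant,venous,44
19,semiauto,resident,arterial,39
19,semiauto,resident,venous,47
19,semiauto,consultant,arterial,37
19,semiauto,consultant,venous,41
20,manual,resident,arterial,48
20,manual,resident,venous,48
20,manual,consultant,arterial,11
20,manual,consultant,venous,12
20,semiauto,resident,arterial,28
20,semiauto,resident,venous,36
20,semiauto,consultant,arterial,20
20,semiauto,consultant,venous,19
21,manual,resident,arterial,25
21,manual,resident,venous,42
21,manual,consultant,arterial,11
21,manual,consultant,venous,12
21,semiauto,resident,arterial,13
21,semiauto,resident,venous,19
21,semiauto,consultant,arterial,10
21,semiauto,consultant,venous,14
22,manual,resident,arterial,41
22,manual,resident,venous,38
22,manual,consultant,arterial,24
22,manual,consultant,venous,29
22,semiauto,resident,arterial,16
22,semiauto,resident,venous,15
22,semiauto,consultant,arterial,20
22,semiauto,consultant,venous,28
23,manual,resident,arterial,69
23,manual,resident,venous,75
23,manual,consultant,arterial,51
23,manual,consultant,venous,47
23,semiauto,resident,arterial,55
23,semiauto,resident,venous,62
23,semiauto,consultant,arterial,52
23,semiauto,consultant,venous,53
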