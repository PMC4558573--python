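# pinned output of the seeded Erdős–Rényi generator (n=30, p=0.2, seed=8)
0	13
0	15
0	17
0	22
0	25
0	3
0	5
1	11
1	19
1	21
1	27
1	28
1	7
1	8
10	15
10	18
10	23
10	26
10	28
10	29
11	24
11	27
11	29
13	14
13	26
13	28
14	19
14	21
14	22
14	24
14	29
15	17
15	25
16	20
16	21
16	25
19	21
19	22
19	24
2	10
2	17
2	19
2	25
2	28
2	4
20	22
20	23
20	24
21	25
22	24
22	26
23	28
23	29
25	29
26	27
26	28
3	10
3	11
3	12
3	19
3	20
3	21
3	27
4	11
4	14
4	18
4	19
4	22
4	6
5	12
5	15
5	25
5	6
5	8
6	21
7	18
7	22
8	27
9	10
9	15
9	20
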