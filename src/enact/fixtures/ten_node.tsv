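# n=10
1	8
2	4
3	2
3	8
4	7
4	8
5	10
6	5
6	9
7	1
7	5
8	6
9	3
9	4
10	8
10	9
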