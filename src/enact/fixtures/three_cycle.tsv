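# n=3
1	2
2	3
3	1
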