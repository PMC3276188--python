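k	n_k
0	1030
1	382
2	74
3	14
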