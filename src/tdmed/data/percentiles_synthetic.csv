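decile,upper_bound_gbp
1,10000
2,13500
3,16500
4,19500
5,23000
6,27000
7,32000
8,39000
9,52000
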