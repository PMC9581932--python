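ploidy	median_relative_amount
1	1.00
2	1.61
3	2.31
4	2.95
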