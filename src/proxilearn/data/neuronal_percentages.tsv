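replicate	pct_neuronal_assigned	pct_neuronal_all
1	93	91
2	91	89
3a	95	92
3b	91	90
4	87	89
5	91	89
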