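feature	pct
intronic	46.4
3'UTR	25.2
exonic	15.4
ncRNA-exonic	4.5
upstream/downstream	4.2
ncRNA-intronic	2.5
5'UTR	1.6
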