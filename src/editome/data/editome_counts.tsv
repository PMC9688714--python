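condition	class	n
naive	A-to-I	775
naive	C-to-U	450
pre-clinical	total	1134
acute	total	891
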