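gene	lnL_alternative	lnL_null	omega2_alternative
nad2	-17791.53	-17791.53	1.000
nad4	-21314.63	-21319.32	209.314
nad5	-35070.30	-35071.85	13.123
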