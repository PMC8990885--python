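# SYNTHETIC stand-in fit table: carbon-on-hydrogen non-elastic cross-section.
# The measured fit knots used by the reference implementation are not
# published numerically; this table is a smooth documented approximation to
# proton-carbon reaction-cross-section systematics (equivalent by detailed
# balance), constructed to be nearly constant above 250 MeV/u.
# E[MeV/u]	sigma[mb]
10	455
15	440
20	420
30	380
40	340
50	310
70	265
95	235
120	222
150	214
200	208
250	205
300	204
350	204
400	204
450	204
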