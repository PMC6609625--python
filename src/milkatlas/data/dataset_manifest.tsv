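dataset_id	source_ref	dim	dryoff_day	technique	max_g	acidification	major_protein_depletion	breed	country	factor_selected	fraction_class	stage_class
D01	R15	1		sucrose_gradient		false	false	Holstein-Friesian	Australia	12 and 24 h post-partum	exosomes	colostrum
D02	R15	2		sucrose_gradient		false	false	Holstein-Friesian	Australia	48 h post-partum	exosomes	colostrum
D03	R15	3		sucrose_gradient		false	false	Holstein-Friesian	Australia	72 h post-partum	exosomes	colostrum
D04	R39	3		sucrose_gradient		false	false	Holstein	China	0 to 5 d post-partum	exosomes	colostrum
D05	R22	1		cream_separation		false	false	Holstein	USA	1 d post-partum	MFGM	colostrum
D06	R22	7		cream_separation		false	false	Holstein	USA	7 d post-partum	MFGM	early
D07	R10	14		cream_separation		false	false	Holstein-Friesian		dry period length	MFGM	early
D08	R40	14		cream_separation		false	false	Holstein	China	Holstein	MFGM	early
D09	R42	2		centrifugation	3000	true	true	Holstein	Brazil	48 h post-partum	skimmed	colostrum
D10	R42	3		centrifugation	3000	true	true	Holstein	Brazil	72 h post-partum	skimmed	colostrum
D11	R41	1		centrifugation	3000	false	false	Holstein-Friesian	Denmark	1 d post-partum	skimmed	colostrum
D12	R17	1		centrifugation	3000	false	false	Holstein-Friesian	Denmark	1 d post-partum	skimmed	colostrum
D13	R17	10		centrifugation	3000	false	false	Holstein-Friesian	Denmark	10 d post-partum	skimmed	early
D14	R13	14		centrifugation	3000	false	false	Holstein-Friesian	Denmark	milk fractionation	skimmed	early
D15	R45	60		centrifugation	3000	false	false	Holstein	USA	low RDP:RUP ratio	skimmed	peak
D16	R45	60		centrifugation	3000	false	false	Holstein	USA	high RDP:RUP ratio	skimmed	peak
D17	R50	120		centrifugation	3000	false	false	Holstein	China	corn-grain based diet	skimmed	mid
D18	R48	120		centrifugation	3000	true	false	Holstein-Friesian	Denmark	3 h post-challenge by Escherichia coli	skimmed	mid
D19	R51	120		centrifugation	3000	false	false	Holstein-Friesian	Australia	Holstein-Friesian	skimmed	mid
D20	R51	120		centrifugation	3000	false	false	Jersey	Australia	Jersey	skimmed	mid
D21	R49	120		centrifugation	3000	false	false	Holstein-Friesian	Spain	healthy	skimmed	mid
D22	R47	120		centrifugation	3000	false	false	Holstein	USA	healthy	skimmed	mid
D23	R41	1		centrifugation	100000	false	false	Holstein-Friesian	Denmark	1 d post-partum	whey	colostrum
D24	R43	3		centrifugation	100000	false	false	Holstein	China	0 to 5 d post-partum	whey	colostrum
D25	R44	0		ultracentrifugation	150000	false	false	Holstein-Friesian	Belgium	calving day	whey	colostrum
D26	R52		3	centrifugation	100000	false	false	Holstein-Friesian	New Zealand	3 d post drying-off	whey	drying_off
D27	R52		8	centrifugation	100000	false	false	Holstein-Friesian	New Zealand	8 d post drying-off	whey	drying_off
D28	R13	14		centrifugation	100000	false	false	Holstein-Friesian	Denmark	milk fractionation	whey	early
D29	R44	9		ultracentrifugation	150000	false	false	Holstein-Friesian	Belgium	9 d post-partum	whey	early
D30	R46	60		ultracentrifugation	150000	true	true	Holstein	USA	Holstein	whey	peak
D31	R46	60		ultracentrifugation	150000	true	true	Holstein	USA	Jersey	whey	peak
D32	R45	60		ultracentrifugation	150000	true	true	Holstein	USA	low RDP:RUP ratio	whey	peak
D33	R45	60		ultracentrifugation	150000	true	true	Holstein	USA	high RDP:RUP ratio	whey	peak
D34	R52	120		centrifugation	100000	false	false	Holstein-Friesian	New Zealand	full lactation	whey	mid
D35	R53	120		centrifugation	100000	false	false		United Kingdom	0 h post-challenge by Streptococcus uberis	whey	mid
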