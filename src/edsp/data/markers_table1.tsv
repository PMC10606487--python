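name	chromosome	theta	n_alleles	bp_range
D11S910	11	0.5	8	249-261
D11S912	11	0.5	8	101-123
D11S925	11	0.5	8	173-199
D11S934	11	0.5	8	230-
D11S968	11	0.5	8	137-155
D11S1984	11	0.5	8	166-206
D11S1392	11	0.5	8	200-220
D11S1999	11	0.5	8	109-137
D11S2000	11	0.5	8	199-235
D11S2371	11	0.5	8	193-213
D11S4464	11	0.5	8	225-249
D17S250	17	0.5	8	151-169
D17S787	17	0.5	8	138-166
D17S789	17	0.5	8	154-170
D17S793	17	0.5	8	95-109
D17S798	17	0.5	8	218-
D17S799	17	0.5	8	186-200
D17S807	17	0.5	8	114-138
D17S809	17	0.5	8	229-247
D17S928	17	0.5	8	135-165
D17S934	17	0.5	8	174-
D17S1290	17	0.5	8	170-210
D17S1293	17	0.5	8	262-290
D17S1301	17	0.5	8	147-163
D17S1303	17	0.5	8	225-245
D17S1308	17	0.5	8	304-316
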