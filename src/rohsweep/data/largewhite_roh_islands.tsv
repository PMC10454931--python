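population	chrom	start_bp	end_bp	length_bp	n_snps	qtl
American	1	43045542	43357270	311728	5	-
American	1	146085059	148974102	2889043	42	S: 145,869,313 E: 173,242,773 Average daily gain
American	4	98912988	102212696	3299708	51	-
American	6	102107540	102337903	230363	4	-
American	6	102717110	102796136	79026	2	-
American	6	102917556	104370915	1453359	23	-
American	6	104981850	110109305	5127455	121	-
American	7	72338896	74402073	2063177	42	S: 72,215,870 E: 87,765,126 Fat area percentage in carcass
American	14	98912988	102212696	3299708	43	-
Canadian	4	44727463	48379816	3652353	54	S: 44,723,094 E: 91,039,884 Ham weight
Canadian	6	105047268	107701419	2654151	64	-
Canadian	7	50032121	52080918	2048797	31	-
Canadian	7	70691786	74260534	3568748	66	S: 70,292,251 E: 83,677,435 Teat number
Canadian	8	22032465	23585036	1552571	29	-
Canadian	8	24568718	25096226	527508	2	S: 24,414,300 E: 25,683,843 Umbilical hernia
Canadian	8	57175682	58758032	1582350	35	S: 56,966,700 E: 67,491,976 Hematocrit
Canadian	14	92778821	94149712	1370891	39	-
Danish	2	71619091	74328649	2709558	33	S: 71,416,758 E: 128,795,277 Leaf fat weight
Danish	5	51535641	54004977	2469336	52	-
Danish	5	54091881	54253706	161825	5	S: 54,354,525 E: 54,411,945 uterine horn length
Danish	6	105105811	107369304	2263493	57	-
Danish	9	83483921	88168152	4684231	111	S: 80,796,751 E: 97,479,874 Immunoglobulin G level
Danish	13	86541183	88583284	2042101	48	S: 86,471,446 E: 118,227,339 Lean meat percentage
Danish	15	76452937	76592155	139218	5	S: 76,167,178 E: 76,761,699 Intramuscular fat content
Danish	15	77669772	79049130	1379358	26	S: 77,173,290 E: 90,664,324 Drip loss
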