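gene_name	accession	pi	mw_kda	aa_count	localization
NtPIP1;1	NP_001313131.1	8.83	30.70	286	PM,C
NtPIP1;2	XP_016508253.1	8.30	30.76	285	PM
NtPIP1;3	AAB04757.1	9.08	30.58	287	PM
NtPIP1;4	NP_001312189.1	8.30	30.80	287	PM
NtPIP1;5	CAA04750.1	8.29	30.82	287	PM
NtPIP1;6	XP_016476491.1	8.99	30.90	287	PM
NtPIP1;7	NP_001312824.1	8.61	30.84	287	PM
NtPIP1;8	NP_001312222.1	8.83	30.82	286	PM
NtPIP1;9	NP_001312921.1	8.96	30.49	284	PM
NtPIP1;10	XP_016458231.1	9.10	30.74	288	PM
NtPIP1;11	XP_016515710.1	8.23	27.31	254	PM
NtPIP1;12	NP_001312721.1	8.99	30.77	287	PM
NtPIP1;13	XP_016510215.1	9.00	30.64	285	PM
NtPIP2;1	AAL33586.1	9.05	30.49	268	PM,C
NtPIP2;2	NP_001313091.1	9.05	30.47	268	PM
NtPIP2;3	NP_001312414.1	9.04	30.48	268	PM
NtPIP2;4	NP_001312350.1	8.87	30.41	283	PM
NtPIP2;5	NP_001312874.1	8.89	30.39	283	PM
NtPIP2;6	XP_016477641.1	9.02	28.49	284	PM
NtPIP2;7	NP_001313061.1	8.98	28.63	284	PM
NtPIP2;8	XP_016476355.1	9.17	28.49	284	PM,C
NtPIP2;9	NP_001312511.1	8.84	30.37	283	PM
NtPIP2;10	XP_016494749.1	8.63	30.32	283	PM
NtPIP2;11	NP_001311701.1	8.19	30.49	285	PM
NtPIP2;12	NP_001312276.1	7.62	30.48	285	PM
NtPIP2;13	NP_001312334.1	6.94	31.23	291	PM
NtPIP2;14	XP_016486700.1	6.94	31.21	291	PM
NtPIP2;15	NP_001312333.1	7.62	30.26	283	PM
NtPIP2;16	XP_016513533.1	7.62	30.30	283	PM
NtPIP2;17	NP_001312464.1	8.21	30.73	287	PM
NtPIP2;18	NP_001313066.1	8.20	30.78	287	PM
NtPIP2;19	NP_001313208.1	7.04	30.16	283	PM
NtPIP2;20	NP_001311719.1	7.04	30.73	287	PM
NtPIP2;21	NP_001311765.1	7.69	30.68	287	PM
NtTIP1;1	BAF95576.1	5.55	25.79	252	PM
NtTIP1;2	NP_001312131.1	5.70	25.80	252	PM,V
NtTIP1;3	NP_001312871.1	5.70	25.73	248	PM
NtTIP1;4	XP_016513281.1	5.91	26.19	248	PM
NtTIP1;5	XP_016501711.1	5.37	25.91	248	PM
NtTIP1;6	XP_016487055.1	5.37	25.90	251	PM
NtTIP1;7	XP_016471957.1	6.04	25.56	251	PM
NtTIP1;8	XP_016495978.1	5.62	25.12	251	PM,V
NtTIP1;9	XP_016450483.1	5.89	25.25	251	PM
NtTIP2;1	NP_001312646.1	5.35	24.94	248	PM,V
NtTIP2;2	XP_016495734.1	5.35	24.99	248	PM
NtTIP2;3	XP_016503582.1	6.00	25.07	248	PM
NtTIP2;4	XP_016480756.1	5.67	25.01	248	PM
NtTIP2;5	XP_016515893.1	5.67	25.02	248	PM
NtTIP2;6	XP_016445220.1	4.85	25.36	250	V
NtTIP2;7	XP_016481958.1	4.85	25.30	250	V
NtTIP2;8	NP_001312940.1	5.66	25.23	250	V
NtTIP2;9	XP_016481922.1	5.66	25.24	250	V
NtTIP2;10	P24422.2	5.32	25.22	250	V
NtTIP3;1	XP_016491554.1	7.07	27.62	260	PM
NtTIP3;2	XP_016491898.1	8.08	27.58	260	PM
NtTIP3;3	XP_016436583.1	7.07	27.41	259	PM
NtTIP3;4	XP_016500896.1	7.07	27.40	259	PM
NtTIP4;1	NP_001311953.1	5.79	25.96	247	V
NtTIP4;2	XP_016441470.1	5.79	25.98	247	V
NtTIP5;1	XP_016462485.1	7.78	25.63	250	PM
NtTIP5;2	XP_016485861.1	7.78	25.59	250	PM
NtNIP1;1	XP_016487110.1	9.08	30.67	288	PM
NtNIP1;2	XP_016445609.1	9.41	32.65	303	PM
NtNIP2;1	XP_016451246.1	8.96	30.49	286	PM
NtNIP3;1	XP_016460638.1	8.29	37.69	337	PM
NtNIP3;2	XP_016515586.1	8.29	37.91	347	PM
NtNIP4;1	XP_016486634.1	8.52	29.73	281	V
NtNIP4;2	XP_016455585.1	8.83	29.12	275	V
NtNIP4;3	XP_016491262.1	7.74	28.43	270	PM
NtNIP4;4	XP_016453373.1	6.89	28.67	271	PM
NtNIP4;5	XP_016456203.1	8.28	29.07	272	PM
NtNIP4;6	XP_016500017.1	7.69	29.16	272	PM
NtNIP5;1	XP_016470302.1	8.63	30.98	297	V
NtNIP5;2	NP_001312819.1	8.87	30.91	297	V
NtNIP5;3	XP_016493176.1	9.86	31.94	304	PM
NtNIP6;1	XP_016435920.1	8.73	34.50	331	V
NtNIP6;2	XP_016438237.1	8.66	32.35	313	PM
NtNIP7;1	XP_016509644.1	7.71	29.58	280	PM
NtNIP7;2	XP_016496646.1	7.78	31.18	293	PM
NtNIP8;1	XP_016468207.1	8.78	29.88	277	V
NtNIP8;2	XP_016451938.1	9.22	34.00	314	PM
NtSIP1;1	XP_016439604.1	9.22	25.06	238	PM
NtSIP1;2	XP_016492107.1	9.55	25.94	242	PM
NtSIP2;1	XP_016496337.1	10.01	26.45	240	PM,C
NtXIP1;1α	NP_001312796	7.70	34.61	325	PM
NtXIP1;1β	Nitab4.5_0000956g0150.1	7.71	34.75	325	PM
NtXIP1;2α	XP_016446694	7.71	34.68	326	PM
NtXIP1;2β	Nitab4.5_0007293g0050.1	7.71	34.54	326	PM
NtXIP2;1	XP_016489264.1	6.05	33.40	313	PM
NtXIP2;2	XP_016488683	8.70	33.07	308	PM
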