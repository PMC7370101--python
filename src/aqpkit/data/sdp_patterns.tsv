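substrate	arR	lb	le	fp	roster
Bo	[AGI][ISV][GA]R	SG[AG]H[ILM]NP[ASV][VLI][TS]	[GS][GA][SG]MNP[AV]R[STC][LF]G	[FIV][TC]A[YF][LFW]	NtNIP5;1, NtXIP1;1–2
CO2	FHTR	SGGHINPAVT	GTGINPARSLG	[MQ]SAFW	NtPIP1;1–2, NtPIP1;4–8, NtPIP1;10, NtPIP1;12–13, NtPIP2;9–10
H2O2	[HFWI][IHV][ATG][VR]	SG[GA]H[VLIF]NP[AV][VI][TS]	G[AGT][SG][MI]NP[AG][VR][ASC][FL]G	[TQFV][ASC]A[YF][WI]	NtPIP1;12–13, NtPIP2;9–21, NtTIP1;1–9, NtTIP2;1–10, NtNIP3;2, NtXIP1;1–2
NH3	[HW][IV][AG]R	SGGH[VLF]NPAVT	G[GA]SMNPARS[FL]G	[FT]SAY[LW]	NtTIP2;1–10, NtTIP4;1–2
Si	GSGR	SGAHMNPAVT	GGSMNPARTL[GA]	[IL]TAYF	NtNIP2;1
U	[HGANI][ISV][AG][RVC]	SG[GA]H[ILVM]NP[AV][VI][TS]	[GS][AG][SG]MNP[AV][RVC][TSC][LF]G	[MTLFVI][SATC]A[YF][WFL]	NtTIP1;1–9, NtTIP4;1–2, NtXIP1;1–2
As	[GAW][VSAI][GA][RV]	SG[AC]H[LIVMF]NP[AS][VI]T	[GS][GA]SMNP[AV]R[ST][LI][AG]	[LIFY][TS]AY[FILM]	NtNIP1;1–2, NtNIP3;1–2, NtNIP4;1–6
Sb	[AGT][IVSA][GA]R	SG[AC]H[LM]NP[SA][VIT][TS]	[GS][GA]SMNP[VA]R[TS]L[GA]	[FYIL][TS]AY[LMF]	-
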