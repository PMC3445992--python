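gene	origin	nj_direction	ml_call	ml_direction	homolog	homolog_lgt	asterisk_note
Msp_0039	LGT	Bacteria->Archaea	LGT	Bacteria->Archaea	None		0
Msp_0042	LGT	Bacteria->Archaea	LGT	DU	None		0
Msp_0044	LGT	DU	LGT	DU	None		0
Msp_0045	Non-LGT	N/A	N/A	N/A	None		0
Msp_0049	Non-LGT	N/A	N/A	N/A	None		1
Msp_0051	Non-LGT	N/A	N/A	N/A	None		0
Msp_0052	Non-LGT	N/A	N/A	N/A	None		0
Msp_0053	Non-LGT	N/A	N/A	N/A	None		0
Msp_0054	Non-LGT	N/A	N/A	N/A	None		0
Msp_0055	LGT	Bacteria->Archaea	LGT	Bacteria->Archaea	None		0
Msp_0056	Non-LGT	N/A	N/A	N/A	None		0
Msp_0057	Non-LGT	N/A	N/A	N/A	None		0
Msp_0080	Non-LGT	N/A	N/A	N/A	None		0
Msp_0101	LGT	Archaea->Bacteria	Non-LGT	N/A	Msm_0836	Non-LGT	0
Msp_0203	LGT	DU	LGT	DU	None		0
Msp_0206	LGT	DU	LGT	DU	Msm_1329	LGT	0
Msp_0207	LGT	Bacteria->Archaea	LGT	Bacteria->Archaea	Msm_1330	LGT	0
Msp_0212	Non-LGT	N/A	N/A	N/A	None		0
Msp_0215	LGT	DU	LGT	DU	None		0
Msp_0218	LGT	Bacteria->Archaea	LGT	Bacteria->Archaea	None		0
Msp_0220	Non-LGT	N/A	N/A	N/A	None		0
Msp_0441	LGT	Bacteria->Archaea	LGT	Bacteria->Archaea	None		0
Msp_0442	LGT	Bacteria->Archaea	LGT	Bacteria->Archaea	Msm_1594	LGT	0
Msp_0492	LGT	DU	LGT	N/A	Msm_1313	Non-LGT	0
Msp_0493	LGT	Bacteria->Archaea	LGT	Bacteria->Archaea	None		0
Msp_0495	LGT	DU	LGT	DU	None		0
Msp_0496	LGT	DU	LGT	DU	None		1
Msp_0500	LGT	DU	LGT	DU	Msm_1312	LGT	1
Msp_0538	LGT	DU	LGT	DU	None		0
Msp_0541	Non-LGT	N/A	N/A	N/A	Msm_1623	Non-LGT	0
Msp_0645	Non-LGT	N/A	N/A	N/A	Msm_0423	Non-LGT	0
Msp_0989	Non-LGT	N/A	N/A	N/A	None		0
Msp_0991	Non-LGT	N/A	N/A	N/A	None		0
Msp_1087	Non-LGT	N/A	N/A	N/A	None		0
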