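gene	annotation	fraction	nj_direction	ml_direction	homolog	homolog_annotation	homolog_lgt	asterisk_note
Msp_0204	Polysaccharide/polyol phosphate ABC transporter permease	2/2	Bacteria->Archaea	Bacteria->Archaea	Msm_1325	Polysaccharide/polyol phosphate ABC transporter, permease component	LGT	0
Msp_0205	Polysaccharide/polyol phosphate ABC transporter ATP-binding protein		Bacteria->Archaea	Bacteria->Archaea	Msm_1326	Polysaccharide/polyol phosphate ABC transporter, ATPase component	LGT	0
Msp_0610	Molybdenum ABC transporter ATP-binding protein	1/1	Direction unknown	Direction unknown	Msm_0593	Multidrug ABC transporter, ATPase component, CcmA	LGT	1
Msp_0808	Peptide ABC transporter ATP-binding protein	2/5	Direction unknown	No LGT	Msm_0304	Peptide/nickel ABC transporter, ATP-binding component, DppF	LGT	0
Msp_0809	Peptide ABC transporter ATP-binding protein		Direction unknown	No LGT	Msm_0303	Peptide/nickel ABC transporter, ATP-binding component, DppD	NO	0
Msp_0810	ABC-type dipeptide transport system, permease protein		No LGT	No LGT	Msm_0302	Peptide/nickel ABC transporter, permease component, DppC	NO	1
Msp_0811	ABC-type dipeptide transport system, permease protein		No LGT	No LGT	Msm_0301	Peptide/nickel ABC transporter, permease component, DppB	NO	1
Msp_0812	ABC-type dipeptide transport system, dipeptide-binding protein		No LGT	No LGT	Msm_0300	Peptide/nickel ABC transporter, solute-binding component	NO	1
Msp_0847	Peptide ABC transporter ATP-binding protein	1/5	Direction unknown	Direction unknown	N/A	N/A	N/A	0
Msp_0848	Peptide ABC transporter ATP-binding protein		No LGT	No LGT	N/A	N/A	N/A	1
Msp_0849	Peptide ABC transporter permease		No LGT	No LGT	N/A	N/A	N/A	1
Msp_0850	Peptide ABC transporter permease		No LGT	No LGT	N/A	N/A	N/A	1
Msp_0851	Peptide ABC transporter solute-binding protein		No LGT	No LGT	N/A	N/A	N/A	1
Msp_0958	Polar amino acid ABC transporter ATP-binding protein	3/3	Bacteria->Archaea	Bacteria->Archaea	Msm_0805	Polar amino acid ABC transporter, ATPase component	LGT	0
Msp_0959	Polar amino acid ABC transporter permease		Bacteria->Archaea	Bacteria->Archaea	Msm_0806	Polar amino acid ABC transporter, permease component	LGT	0
Msp_0960	Polar amino acid ABC transporter periplasmic substrate-binding protein		Bacteria->Archaea	Bacteria->Archaea	Msm_0807	Polar amino acid ABC transporter, substrate-binding component	LGT	0
Msp_1000	Nitrate/sulfonate/bicarbonate transport system ABC transporter ATP-binding protein	2/3	Bacteria->Archaea	Direction unknown	Msm_0290	Nitrate/sulfonate/bicarbonate ABC transporter, ATPase component, TauB	LGT	0
Msp_1001	Nitrate/sulfonate/bicarbonate ABC transporter permease		Bacteria->Archaea	Direction unknown	Msm_0291	Nitrate/sulfonate/bicarbonate ABC transporter, permease component, TauC	NO	0
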