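trajectory	subtype	patient_id	probability_score	fusion_gene	critical_genes_diagnosis	critical_genes_first_relapse	critical_genes_second_relapse
persistent	B-other	ALL_128	1	na	BIRC7, SH2B3, ETV6, PLAA	CDKN2A, BIRC7, SH2B3, ETV6, PLAA, PMS2, NF1, IKZF1	CDKN2A, BIRC7, SH2B3, ETV6, PLAA, PMS2, NF1, IKZF1
persistent	HeH	ALL_464	0.1	na	PTPN11,NRAS	na	na
persistent	HeH	ALL_832	0.8	na	na	CREBBP	CREBBP, NRAS
rising	t(12;21)	ALL_124	1	ETV6-RUNX1	na	na	na
rising	DUX4-rearranged	ALL_205	1	DUX4-IGH	NRAS, GATAD2B	CDKN2A, KDM6A, NF1	na
rising	MEF2D-rearranged	ALL_244	1	MEF2D-BCL9	KRAS, IKZF1, NR3C1	CDKN2A, CREBBP, EP300, IKZF1, NR3C1	CDKN2A, EP300, IKZF1, NR3C1, PLAA
rising	ZNF384-rearranged	ALL_257	1	na	CDKN2A, ETV6,CREBBP, ZNF384, UBA2, MSI2	CDKN2A, ETV6,CREBBP, ZNF384, UBA2, MSI2	na
rising	T-ALL	ALL_358	1	na	IKZF1, NOTCH1, HIST1H4J, FBXW7, MYO9A	CDKN2A, IKZF1, NT5C2, NRAS, ARID1A, NOTCH1, HIST1H4J, PALM2	na
rising	T-ALL	ALL_388	1	STIL-TAL1	CDKN2A, FBXW7, MSI2	CDKN2A, FBXW7, NT5C2, NR3C1, MSI2	na
rising	KMT2A-rearranged	ALL_5	0.99	AFF1-KMT2A	na	EBF1, ZCCHC7	CDKN2A, EBF1, ZCCHC7
rising	dic(9;20)	ALL_680	0.4	IKZF1-IGK	CDKN2A, KRAS, PLAA, CSK	CDKN2A,PLAA, NF1, CSK	na
rising	ZNF384-rearranged	ALL_8	1	ZNF384-TAF15	CDKN2A, KDM6A, NRAS, ATRX, PLAA, CHRAC1, MYC	CDKN2A, KDM6A, ATRX, PLAA, CHRAC1, MYC	na
rising	MPAL	ALL_827	1	ETV6-TSL	NRAS	na	na
rising	t(12;21)	ALL_835	1	ETV6-RUNX1	NRAS	na	na
rising	HeH	ALL_839	0.6	na	NRAS, PALM2	NRAS	na
founding	t(12;21)	ALL_109	1	ETV6-RUNX1	HDAC2	HDAC2, CREBBP, NT5C2, GATAD2B, PRPS1	HDAC2, BCORL1,PRPS1
founding	KMT2A-rearranged	ALL_202	0.7	AFF1-KMT2A	na	na	na
founding	HeH	ALL_210	0.07	na	PTPN11,CSK	PTPN11,KRAS, CSK, PALM2	na
founding	B-other group	ALL_24	1	PAX5-ZCCHC7	IKZF1, EBF1	EBF1	na
founding	B-other	ALL_27	0.98	CRLF2-P2RY8	HIST1H1D, IL7R	KRAS, SH2B3, EZH2, IDH1, EBF1, PLAA, IKZF1, ATRX, HIST1H1D	KRAS, SH2B3, CREBBP, EZH2, IDH1, EBF1, PLAA, IKZF1, ATRX, HIST1H1D
founding	iAMP21	ALL_317	1	na	ETV6, PTEN, PAX5, CHRAC1	PAX5, CHRAC1	na
founding	HeH	ALL_380	1	na	IKZF1, ETV6	IKZF1, ETV6	na
founding	HeH	ALL_48	1	na	KRAS	PLAA	na
founding	T-ALL	ALL_836	1	na	HIST1H3I	HIST1H3I, NT5C2	HIST1H3I, NT5C2
founding	HeH	ALL_837	1	na	UBA2	NRAS	na
founding	B-other	ALL_838	1	CRLF2-P2RY8	CDKN2A	CDKN2A, PAX5, NRAS	na
undetermined	B-other group	ALL_834	na	CRLF2-P2RY8	IKZF1, ETV6	na	na
undetermined	HeH	ALL_831	na	na	KRAS	PTPN11, MYO9A, CHRAC1	Na
undetermined	T-ALL	ALL_833	na	TAL2-TRB	CDKN2A, PTEN, PALM2, USP7	CDKN2A, PALM2, PTEN	CDKN2A, PTEN,PALM2, USP7
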