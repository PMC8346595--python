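patient_id	immunophenotype	subtype_diagnosis	subtype_revised	risk_group	time_to_first_relapse_months	first_relapse_on_off_therapy	time_to_second_relapse_months	dead_or_alive	bmt_after_first_relapse
ALL_5	BCP-ALL	KMT2A-rearranged	KMT2A-rearranged	Infant	28	Off	40	D	yes
ALL_202	BCP-ALL	KMT2A-rearranged	KMT2A-rearranged	Infant	5	On	na	D	no
ALL_680	BCP-ALL	dic(9;20)	dic(9;20)	HR	35	Off	na	A	no
ALL_205	BCP-ALL	normal	DUX4-rearranged	IR	65	Off	na	A	no
ALL_831	BCP-ALL	HeH	HeH	HR	55	Off	na	A	no
ALL_832	BCP-ALL	HeH	HeH	SR	39	Off	48	D	yes
ALL_837	BCP-ALL	HeH	HeH	SR	40	Off	na	A	no
ALL_48	BCP-ALL	HeH	HeH	IR	38	Off	na	A	no
ALL_210	BCP-ALL	HeH	HeH	SR	48	Off	na	A	no
ALL_839	BCP-ALL	HeH	HeH	HR	20	On	na	A	no
ALL_380	BCP-ALL	HeH	HeH	IR	47	Off	na	A	no
ALL_464	BCP-ALL	HeH	HeH	HR	28	Off	na	D	no
ALL_317	BCP-ALL	iAMP21	iAMP21	IR	44	Off	na	A	no
ALL_838	BCP-ALL	normal	B-other group	IR	45	Off	na	D	no
ALL_24	BCP-ALL	B-other group	B-other group	HR	27	Off	na	D	no
ALL_128	BCP-ALL	B-other group	B-other group	IR	38	Off	61	D	no
ALL_244	BCP-ALL	B-other group	MEF2D-rearranged	HR	10	On	19	D	no
ALL_827	MPAL	ALL/AML	MPAL	HR	18	On	na	D	no
ALL_834	BCP-ALL	normal	B-other group	SR	37	Off	64	D	no
ALL_27	BCP-ALL	normal	B-other group	IR	85	Off	100	D	no
ALL_833	T-ALL	T-ALL	T-ALL	HR	5	On	9	D	no
ALL_836	T-ALL	T-ALL	T-ALL	HR	18	On	22	A	no
ALL_358	T-ALL	T-ALL	T-ALL	HR	18	On	na	D	no
ALL_388	T-ALL	T-ALL	T-ALL	HR	14	On	Na	A	no
ALL_835	BCP-ALL	t(12;21)	t(12;21)	SR	53	Off	Na	A	no
ALL_109	BCP-ALL	t(12;21)	t(12;21)	HR	24	Off	45	D	yes
ALL_124	BCP-ALL	t(12;21)	t(12;21)	SR	35	Off	Na	D	no
ALL_257	BCP-ALL	normal	ZNF384-rearranged	IR	38	Off	Na	A	no
ALL_8	BCP-ALL	B-other group	ZNF384-rearranged	IR	40	Off	Na	A	no
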