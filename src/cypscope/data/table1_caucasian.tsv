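cyp	allele	aa_changes	activity	test_drug	source_ids	Caucasian
1A1	*2A	I462V	increase	17β-estradiol	19514967	19.0
1A2	*1F	none	higher inducibility	Omeprazole	12534642;22299824	33.3
1A2	*1D	none	decrease	Clozapine	12534642;20797314	4.82
2C9	*2	R144C	decrease	Warfarin	15284536	19.0% *1/*2 1.6% *2/*2 1.8 % *2/*3
2C9	*3	I359L	decrease	Tolbutamide	11678789	9.0
2C19	*2	Splicing I331V defect	decrease	Clopidogrel	10460072	16.0
2C19	*17	I331V	increase	Omeprazole	21247447	18.0
2D6	*3	N166D;259 Frameshift	decrease	Debrisoquine	9012401	2.04
2D6	*4	P34S;L91M;H94R;Splicing defect;S486T	decrease	Dextromethorphan	9012401	20.7
2D6	*4D	P34S;Splicing defect;S486T	decrease	Bufuralol	11266079	3.4
2D6	*4L	P34S;Splicing defect;S486T	decrease	Bufuralol	11266079	4.5
2D6	*5	CYP2D6 deleted	no enzyme		9511177	4.1
2D6	*6	118Frameshift	nonfunctional		9511177	1.3
2D6	*7	H324P	decrease	Sparteine	9089660	1.0
2D6	*9	K281del	decrease	Sparteine	9511177	2.0
2D6	*10	P34S;S486T	decrease	Metoprolol	9511177;11505219	8.0
2D6	*41	R296C;Splicing defect;S486T	decrease (expression)		15289790	8.0
2A6	*12	10 aa substitutions	decreased (expression)		16041240	2.9
2A6	*1B	none	increase	Caffeine	22850738	32.6
2A6	*2	L160H	decrease	Nicotine	11259354	2.3
2A6	*4	CYP2A6 deleted	no enzyme		11259354	1.0
2A6	*9	(TATA box)	decreased	Nicotine	15475735	7.1
3A4	*17	F189S	decrease	Testosterone	11714865	2.0
3A4	*1B	none	increase (transcription)	Tacrolimus	12692107	17.0
3A4	*2	S222P	decrease	Nifedipine	10668853	2.7
3A5	*3C	Splicing defect	decrease	Sirolimus	17162466	81.3
3A5	*3k/*10	Splicing defect;F446S	decrease	Nifedipine	12893984	2.0
3A7	*2	T409R	increase	Dehydroepiandrosterone	15903124	8.0
2B6	*2	R22C	increase	Artemether	21746968;12242601	5.3
2B6	*5	R487C	decrease	Nirvanol	11470993	14.0
2B6	*4	K262R	increase	Bupropion	14515060	5.0
2B6	*6	Q172H;K262R	decrease (expression)	Cyclophosphamide	14515060	25.2
2B6	*7	Q172H;K262R;R487C	decrease	7-ethoxy-4-trifluoromethylcoumarin	12242601;14551287	3.0
2B6	*22	none	increase (transcription)		15722458	3.0
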