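Locus	Exon	Reference	FwdRegion	FwdPos	RevRegion	RevPos	Length	Pool	PoolingFactor
A	2	A*01:01:01:01	exon1	51-67	intron2	66-83	496	long	1
A	3	A*01:01:01:01	intron2	95-116	intron3	65-83	385	long	1
A	4	A*01:01:01:01	intron3	75-95	intron4	76-91	393	long	1
B	1	B*07:02:01:01	5NCR	35-55	intron1	45-59	158	short	0.5
B	2	B*07:02:01:01	intron1	45-59	intron2	25-43	389	long	1
B	3	B*07:02:01:01	intron2	95-109	intron3	36-52	354	long	1
B	4	B*07:02:01:01	intron3	70-88	exon5	27-45	452	long	1
C	1	C*01:02:01:01	5NCR	30-50	intron1	42-62	166	short	0.5
C	2	C*01:02:01:01	intron1	42-62	intron2	42-58	407	long	1
C	3	C*01:02:01:01	intron2	85-105	intron3	65-83	395	long	1
C	4	C*01:02:01:01	intron3	70-87	intron4	76-94	401	long	1
C	7	C*01:02:01:01	intron6	62-80	exon8	14-33	140	short	0.5
DRB	2	DRB1*01:01:01	intron1	168-189	exon2	250-270	303	long	6
DRB	3	DRB1*01:01:01	intron2	120-140	intron3	1-20	333	long	1
DQB1	2	DQB1*02:01:01	intron1|exon2	191-200|1-9	exon2|intron2	268-270|1-16	296	short	0.5
DQB1	3	DQB1*02:01:01	exon3	43-62	intron3	1-27	267	short	0.5
DPB1	2	DPB1*03:01:01	intron1	168-195	intron2	3-27	330	long	1
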