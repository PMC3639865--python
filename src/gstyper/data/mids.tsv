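MID	Sequence
MID01	GCCTTAGTGG
MID02	CAGAGGTCAC
MID03	CCTTGGCCTT
MID04	AGCGGTCTGT
MID05	AGCCTTTGGT
MID06	CGTATGATAT
MID07	GCATTTAAGC
MID08	TAAGTGTAGA
MID09	TCGTACGACA
MID10	CACCACTAGA
MID11	CTCTCCTAGA
MID12	CGAGTTGTAC
MID13	TGTTTATTCT
MID14	CCTTATAATT
MID15	GTAAGTGCAT
MID16	CTTCCCCTTA
MID17	GCCCCGTGCT
MID18	AGGGAAGTTA
MID19	TCAGGGCGAT
MID20	CCGGGGTATC
MID21	GAACTGAGTT
MID22	CCCTATTGCC
MID23	CACGTCGCTG
MID24	TCTGGGGGGT
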