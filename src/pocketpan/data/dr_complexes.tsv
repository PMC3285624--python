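# Reference set: 32 solved HLA-DR/peptide complexes with known binding cores.
# Transcribed from published crystal-structure records (PDB); core_start is
# the 0-based offset of the 9-residue binding core within the peptide.
pdb_id	allele	peptide	core_start
1AQD	DRB1*01:01	VGSDWRFLRGYHQYA	4
1PYW	DRB1*01:01	XFVKQNAAALX	1
1KLG	DRB1*01:01	GELIGILNAAKVPAD	3
2FSE	DRB1*01:01	AGFKGEQGPKGEPG	2
1KLU	DRB1*01:01	GELIGTLNAAKVPAD	3
1SJH	DRB1*01:01	PEVIPMFSALSEG	2
1SJE	DRB1*01:01	PEVIPMFSALSEG	2
1T5W	DRB1*01:01	AAYSDQATPLLLSPR	2
1T5X	DRB1*01:01	AAYSDQATPLLLSPR	2
2IAN	DRB1*01:01	GELIGTLNAAKVPAD	3
2IAM	DRB1*01:01	GELIGILNAAKVPAD	3
2IPK	DRB1*01:01	XPKWVKQNTLKLAT	3
1FYT	DRB1*01:01	PKYVKQNTLKLAT	2
1R5I	DRB1*01:01	PKYVKQNTLKLAT	2
1HXY	DRB1*01:01	PKYVKQNTLKLAT	2
1JWM	DRB1*01:01	PKYVKQNTLKLAT	2
1JWS	DRB1*01:01	PKYVKQNTLKLAT	2
1JWU	DRB1*01:01	PKYVKQNTLKLAT	2
1LO5	DRB1*01:01	PKYVKQNTLKLAT	2
2ICW	DRB1*01:01	PKYVKQNTLKLAT	2
2OJE	DRB1*01:01	PKYVKQNTLKLAT	2
2G9H	DRB1*01:01	PKYVKQNTLKLAT	2
1A6A	DRB1*03:01	PVSKMRMATPLLMQA	4
1J8H	DRB1*04:01	PKYVKQNTLKLAT	2
2SEB	DRB1*04:01	AYMRADAAAGGA	2
1BX2	DRB1*15:01	ENPVVHFFKNIVTPR	4
1YMM	DRB1*15:01	ENPVVHFFKNIVTPRGGSGGGGG	4
2Q6W	DRB3*01:01	AWRSDEALPLGS	1
3C5J	DRB3*02:01	QVIILNHPGQISA	3
1FV1	DRB5*01:01	NPVVHFFKNIVTPRTPPPSQ	6
1H15	DRB5*01:01	GGVYHFVKKHVHES	3
1ZGL	DRB5*01:01	VHFFKNIVTPRTPGG	3
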