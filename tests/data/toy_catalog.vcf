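##fileformat=VCFv4.2
##contig=<ID=toy,length=120>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	TOY1
toy	6	.	C	A	.	PASS	.	GT	0/1
toy	7	.	G	A	.	PASS	.	GT	0/1
toy	22	.	C	G	.	PASS	.	GT	0/1
toy	44	.	C	T	.	PASS	.	GT	0/1
toy	49	.	C	T	.	PASS	.	GT	0/1
toy	63	.	C	A	.	PASS	.	GT	0/1
toy	66	.	G	C	.	PASS	.	GT	0/1
toy	81	.	C	T	.	PASS	.	GT	0/1
toy	97	.	C	G	.	PASS	.	GT	0/1
toy	101	.	C	T	.	PASS	.	GT	0/1
toy	4	.	T	C	.	PASS	.	GT	0/1
toy	30	.	T	A	.	PASS	.	GT	0/1
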