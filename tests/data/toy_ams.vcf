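##fileformat=VCFv4.2
##contig=<ID=toy,length=120>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	TOY1
toy	10	.	C	T	.	PASS	.	GT	0/1
toy	19	.	C	T	.	PASS	.	GT	0/1
toy	79	.	C	T	.	PASS	.	GT	0/1
toy	115	.	C	T	.	PASS	.	GT	0/1
toy	35	.	C	G	.	PASS	.	GT	0/1
toy	60	.	G	A	.	PASS	.	GT	0/1
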