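##fileformat=VCFv4.2
##synthetic=true
##description=Hand-constructed toy variant set for the candidate-variant filter: 12 records around the chr1 critical interval, designed so exactly two rare non-synonymous variants are homozygous in the proband and exactly one cosegregates.
##INFO=<ID=Gene,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=Consequence,Number=1,Type=String,Description="Predicted consequence">
##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	F	M	IND12	IND17	IND13
chr1	108900000	var_chan1	C	A	99	PASS	Gene=CHAN1;Consequence=missense_variant;AF=0.0001	GT	0/1	0/1	1/1	1/1	0/1
chr1	109142651	var_orfX	G	T	99	PASS	Gene=ORFX;Consequence=missense_variant;AF=0.0002	GT	0/1	0/1	1/1	0/1	0/1
chr1	108850000	var_syn	T	C	99	PASS	Gene=CHAN1;Consequence=synonymous_variant;AF=0.0001	GT	0/1	0/1	1/1	1/1	0/1
chr1	108950000	var_common	A	G	99	PASS	Gene=CHAN1;Consequence=missense_variant;AF=0.15	GT	0/1	0/1	1/1	1/1	0/1
chr1	109050000	var_het	G	C	99	PASS	Gene=ORFX;Consequence=missense_variant;AF=0.0003	GT	0/0	0/1	0/1	0/1	0/0
chr1	109100000	var_intron	C	T	99	PASS	Gene=CHAN1;Consequence=intron_variant;AF=0.0001	GT	0/1	0/1	1/1	1/1	0/1
chr1	108820609	var_left	A	T	99	PASS	Gene=UPSTR;Consequence=missense_variant;AF=0.0001	GT	0/1	0/1	1/1	1/1	0/1
chr1	109142652	var_right	T	G	99	PASS	Gene=DNSTR;Consequence=missense_variant;AF=0.0001	GT	0/1	0/1	1/1	1/1	0/1
chr1	108870000	var_stop	C	T	99	PASS	Gene=CHAN1;Consequence=stop_gained;AF=0.0001	GT	0/0	0/1	0/1	0/0	0/0
chr1	109020000	var_ref	G	A	99	PASS	Gene=ORFX;Consequence=missense_variant;AF=0.0004	GT	0/0	0/0	0/0	0/0	0/0
chr1	108990000	var_noanno	A	C	99	PASS	Gene=CHAN1	GT	0/1	0/1	1/1	1/1	0/1
chr2	108900000	var_chr2	C	G	99	PASS	Gene=OTHER;Consequence=missense_variant;AF=0.0001	GT	0/1	0/1	1/1	1/1	0/1
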