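##fileformat=VCFv4.2
##source=refugia-test-fixture (synthetic)
##INFO=<ID=LOC,Number=1,Type=String,Description="RAD locus identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##contig=<ID=L01>
##contig=<ID=L02>
##contig=<ID=L03>
##contig=<ID=L04>
##contig=<ID=L05>
##contig=<ID=L06>
##contig=<ID=L07>
##contig=<ID=L08>
##contig=<ID=L09>
##contig=<ID=L10>
##contig=<ID=L11>
##contig=<ID=L12>
##contig=<ID=L13>
##contig=<ID=L14>
##contig=<ID=L15>
##contig=<ID=L16>
##contig=<ID=L17>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	a1	a2	a3	b1	b2	b3
L01	1	L01_1	A	T	.	PASS	LOC=L01	GT:DP:GQ	0/0:30:99	0/1:30:99	0/0:30:99	1/1:30:99	0/0:30:99	0/1:30:99
L02	1	L02_1	A	T	.	PASS	LOC=L02	GT:DP:GQ	0/1:8:99	0/0:30:99	0/0:30:99	0/0:30:99	1/1:30:99	0/0:30:99
L03	1	L03_1	A	T	.	PASS	LOC=L03	GT:DP:GQ	0/1:9:99	0/0:51:99	0/0:30:99	0/0:30:99	1/1:30:99	0/0:30:99
L04	1	L04_1	A	T	.	PASS	LOC=L04	GT:DP:GQ	0/1:30:19	0/0:30:19	0/1:30:19	0/0:30:19	0/1:30:19	0/0:30:19
L05	1	L05_1	A	T	.	PASS	LOC=L05	GT:DP:GQ	0/1:30:99	0/1:30:99	0/1:30:99	0/1:30:99	0/1:30:99	0/0:30:99
L06	1	L06_1	A	T	.	PASS	LOC=L06	GT:DP:GQ	0/1:30:99	0/1:30:99	0/1:30:99	0/1:30:99	0/0:30:99	1/1:30:99
L07	1	L07_1	A	T	.	PASS	LOC=L07	GT:DP:GQ	0/1:30:99	0/1:30:99	0/1:30:99	0/0:30:99	0/0:30:99	1/1:30:99
L08	1	L08_1	A	T	.	PASS	LOC=L08	GT:DP:GQ	0/1:30:99	0/0:30:99	0/0:30:99	0/0:30:99	0/0:30:99	1/1:30:99
L08	2	L08_2	A	T	.	PASS	LOC=L08	GT:DP:GQ	0/0:30:99	0/1:30:99	0/0:30:99	0/0:30:99	0/0:30:99	1/1:30:99
L08	3	L08_3	A	T	.	PASS	LOC=L08	GT:DP:GQ	0/0:30:99	0/0:30:99	0/1:30:99	0/0:30:99	0/0:30:99	1/1:30:99
L09	1	L09_1	A	T	.	PASS	LOC=L09	GT:DP:GQ	0/1:10:99	0/0:50:99	0/0:30:99	1/1:30:99	0/0:30:99	0/0:30:99
L10	1	L10_1	A	T	.	PASS	LOC=L10	GT:DP:GQ	0/1:30:20	0/0:30:20	0/0:30:20	1/1:30:20	0/0:30:20	0/0:30:20
L11	1	L11_1	A	T	.	PASS	LOC=L11	GT:DP:GQ	0/1:8:99	0/1:30:99	0/1:30:99	0/1:30:99	0/0:30:99	0/0:30:99
L12	1	L12_1	A	T	.	PASS	LOC=L12	GT:DP:GQ	0/1:30:99	0/1:30:99	0/1:30:99	0/1:30:99	0/1:30:99	0/1:30:99
L12	2	L12_2	A	T	.	PASS	LOC=L12	GT:DP:GQ	0/1:30:99	0/0:30:99	0/0:30:99	0/0:30:99	0/0:30:99	1/1:30:99
L13	1	L13_1	A	T	.	PASS	LOC=L13	GT:DP:GQ	1/1:30:99	1/1:30:99	1/1:30:99	0/0:30:99	0/0:30:99	0/0:30:99
L14	1	L14_1	A	T	.	PASS	LOC=L14	GT:DP:GQ	0/0:30:99	0/1:30:99	0/1:30:99	0/0:30:99	0/0:30:99	0/0:30:99
L15	1	L15_1	A	T	.	PASS	LOC=L15	GT:DP:GQ	0/1:30:99	0/0:30:99	1/1:30:99	0/1:30:99	0/0:30:99	0/0:30:99
L16	1	L16_1	A	T	.	PASS	LOC=L16	GT:DP:GQ	0/0:30:99	0/0:30:99	0/1:10:99	0/0:50:99	1/1:30:99	0/1:30:99
L17	1	L17_1	A	T	.	PASS	LOC=L17	GT:DP:GQ	0/1:30:99	1/1:30:99	0/0:30:99	0/1:30:99	0/1:8:99	0/0:30:99
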