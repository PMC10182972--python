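# BRCA1/2 coding homopolymer catalogue (runs of >=6 identical bases), GRCh37/hg19.
# Coordinates 1-based inclusive; base is in coding-strand sense (BRCA1 is minus-strand).
# BRCA2 runs downstream of c.9976 (beyond codon 3326) are excluded by policy.
# genomic_end of BRCA2 c.988_994 is set from the 7-bp coding interval
# (same-exon offset arithmetic from c.951 at 32,906,566).
gene	transcript	chromosome	genomic_start	genomic_end	cds_start	cds_end	length	base
BRCA1	NM_007294.3	17	41256251	41256256	324	329	6	A
BRCA1	NM_007294.3	17	41247865	41247870	663	668	6	A
BRCA1	NM_007294.3	17	41246532	41246538	1010	1016	7	A
BRCA1	NM_007294.3	17	41245587	41245594	1954	1961	8	A
BRCA1	NM_007294.3	17	41244219	41244224	3324	3329	6	A
BRCA2	NM_000059.3	13	32890628	32890633	31	36	6	T
BRCA2	NM_000059.3	13	32906566	32906571	951	956	6	A
BRCA2	NM_000059.3	13	32906603	32906609	988	994	7	A
BRCA2	NM_000059.3	13	32907203	32907208	1588	1593	6	A
BRCA2	NM_000059.3	13	32907421	32907428	1806	1813	8	A
BRCA2	NM_000059.3	13	32910662	32910667	2170	2175	6	A
BRCA2	NM_000059.3	13	32911074	32911080	2582	2588	7	A
BRCA2	NM_000059.3	13	32911322	32911327	2830	2835	6	A
BRCA2	NM_000059.3	13	32911443	32911449	2951	2957	7	A
BRCA2	NM_000059.3	13	32912346	32912352	3854	3860	7	A
BRCA2	NM_000059.3	13	32912656	32912661	4164	4169	6	T
BRCA2	NM_000059.3	13	32912771	32912776	4279	4284	6	T
BRCA2	NM_000059.3	13	32913080	32913085	4588	4593	6	A
BRCA2	NM_000059.3	13	32913559	32913565	5067	5073	7	A
BRCA2	NM_000059.3	13	32913784	32913789	5292	5297	6	A
BRCA2	NM_000059.3	13	32913837	32913843	5345	5351	7	A
BRCA2	NM_000059.3	13	32914070	32914075	5578	5583	6	A
BRCA2	NM_000059.3	13	32914860	32914865	6368	6373	6	A
BRCA2	NM_000059.3	13	32929162	32929167	7172	7177	6	A
BRCA2	NM_000059.3	13	32937355	32937360	8016	8021	6	A
BRCA2	NM_000059.3	13	32953633	32953639	8934	8940	7	A
BRCA2	NM_000059.3	13	32954023	32954030	9090	9097	8	A
BRCA2	NM_000059.3	13	32954273	32954279	9247	9253	7	A
BRCA2	NM_000059.3	13	32972590	32972595	9940	9945	6	A
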