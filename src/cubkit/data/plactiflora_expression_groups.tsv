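# Published codon usage comparison between the 5% highest- and 5% lowest-CAI
# gene sets of the Paeonia lactiflora (herbaceous peony) transcriptome CDS
# collection (24,216 CDS). One row per sense codon (RNA labels): pooled codon
# count N and the reported group RSCU, for each group; `starred` marks codons
# the original analysis reported as significantly more frequent (p < 0.01) in
# the highly expressed set.
aa	codon	high_rscu	high_n	low_rscu	low_n	starred
Ala	GCA	1.245	3868	1.296	10358	0
Ala	GCC	0.888	2761	0.610	4878	1
Ala	GCG	0.471	1464	0.305	2439	0
Ala	GCU	1.396	4338	1.789	14297	1
Arg	AGA	1.582	2545	1.939	8781	1
Arg	AGG	1.478	2378	1.552	7025	0
Arg	CGA	0.831	1338	0.641	2901	0
Arg	CGC	0.582	936	0.481	2177	0
Arg	CGG	0.648	1042	0.492	2228	0
Arg	CGU	0.880	1416	0.895	4054	0
Asn	AAC	0.882	3785	0.627	6592	0
Asn	AAU	1.118	4801	1.373	14443	0
Asp	GAC	0.742	3791	0.529	7071	0
Asp	GAU	1.258	6427	1.471	19638	0
Cys	UGC	0.949	1812	0.748	2950	1
Cys	UGU	1.051	2005	1.252	4937	1
Gln	CAA	1.086	3875	1.099	10044	0
Gln	CAG	0.914	3259	0.901	8230	0
Glu	GAA	1.038	6811	1.112	18684	0
Glu	GAG	0.962	6315	0.888	14916	0
Gly	GGA	1.195	3801	1.270	10495	1
Gly	GGC	0.733	2333	0.546	4515	0
Gly	GGG	0.849	2699	0.779	6443	0
Gly	GGU	1.223	3890	1.405	11615	0
His	CAC	0.871	2065	0.609	3419	0
His	CAU	1.129	2679	1.391	7818	0
Ile	AUA	0.765	2676	0.730	5857	1
Ile	AUC	0.939	3286	0.632	5066	1
Ile	AUU	1.296	4532	1.638	13133	0
Phe	UUC	0.939	4017	0.665	6011	1
Phe	UUU	1.061	4535	1.335	12077	1
Leu	CUA	0.637	1889	0.510	3679	0
Leu	CUC	1.036	3071	0.662	4778	0
Leu	CUG	0.757	2244	0.671	4848	0
Leu	CUU	1.343	3981	1.621	11707	1
Leu	UUA	0.838	2486	0.893	6449	0
Leu	UUG	1.389	4119	1.643	11862	0
Lys	AAA	0.911	6111	0.925	13915	0
Lys	AAG	1.089	7299	1.075	16161	0
Met	AUG	1.000	4764	1.000	10846	0
Pro	CCA	1.376	3278	1.458	8919	1
Pro	CCC	0.779	1855	0.590	3608	1
Pro	CCG	0.606	1444	0.383	2340	0
Pro	CCU	1.239	2953	1.569	9600	0
Ser	AGC	0.807	2057	0.573	4176	1
Ser	AGU	1.031	2628	1.074	7834	0
Ser	UCA	1.218	3105	1.427	10405	1
Ser	UCC	0.961	2450	0.670	4885	1
Ser	UCG	0.620	1580	0.431	3144	1
Ser	UCU	1.365	3481	1.826	13318	0
Thr	ACA	1.198	2842	1.316	7458	1
Thr	ACC	1.047	2485	0.745	4221	0
Thr	ACG	0.491	1166	0.365	2069	0
Thr	ACU	1.263	2997	1.574	8922	0
Trp	UGG	1.000	2675	1.000	5315	0
Tyr	UAC	0.917	2611	0.702	4462	1
Tyr	UAU	1.083	3082	1.298	8257	1
Val	GUA	0.711	2143	0.642	5096	1
Val	GUC	0.801	2412	0.569	4523	0
Val	GUG	1.106	3331	0.930	7389	1
Val	GUU	1.382	4163	1.859	14764	0
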