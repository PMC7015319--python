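# Theoretical tRNA copy numbers for E. coli K12 matched to ORF codon usage,
# tabulated at growth rates mu = 0.70, 1.07 and 2.50 doublings per hour.
# Columns: tRNA, count@mu0.70, count@mu1.07, count@mu2.50
Ala1B	4718	9437	37748
Ala2	1745	3491	13964
Arg2	3177	6354	25416
Arg3	366	733	2932
Arg4	138	276	1104
Arg5	76	153	612
Asn	2666	5333	21332
Asp1	3488	6977	27908
Cys	792	1584	6336
Gln1	1047	2094	8376
Gln2	1972	3945	15780
Glu2	3917	7834	31336
Gly1	474	949	3796
Gly2	815	1631	6524
Gly3	3709	7418	29672
His	1541	3083	12332
Ile1	3794	7588	30352
Ile2	289	579	2316
Leu1	1870	3740	14960
Leu2	1509	3019	12076
Leu3	2010	4020	16080
Leu4	621	1243	4972
Leu5	1251	2502	10008
Lys	2992	5985	23940
Metm	1701	3403	13612
Phe	2645	5290	21160
Pro1	943	1887	7548
Pro2	503	1007	4028
Pro3	1567	3135	12540
Ser1	1091	2182	8728
Ser2	398	796	3184
Ser3	1687	3374	13496
Ser5	760	1520	6080
Thr1	767	1535	6140
Thr2	686	1373	5492
Thr3	767	1535	6140
Thr4	1440	2880	11520
Trp	1040	2080	8320
Tyr1	964	1929	7716
Tyr2	964	1929	7716
Val1	2988	5977	23908
Val2	1816	3632	14528
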