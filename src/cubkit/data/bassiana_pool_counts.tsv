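# High-bias (lowest-ENC) and low-bias (highest-ENC) pooled codon counts of
# Beauveria bassiana genes, transcribed from the optimal-codon table of the
# published genome-wide codon-usage study of assembly ASM28067v1.
# printed_rscu is the within-pool RSCU printed next to each count.
# ambiguous=1 marks two low-pool cells whose print was garbled
# ("0.9 7 4782", "1.3 9 4816"); they are stored under the natural reading
# (0.97/4782, 1.39/4816) and excluded from fixture-based assertions.
codon	pool	count	printed_rscu	ambiguous
UUU	high	3493	0.99	0
UUC	high	3581	1.01	0
UUA	high	52	0.02	0
UUG	high	546	0.21	0
CUU	high	956	0.37	0
CUC	high	9236	3.53	0
CUA	high	351	0.13	0
CUG	high	4564	1.74	0
AUU	high	3160	1.09	0
AUC	high	5373	1.85	0
AUA	high	159	0.05	0
AUG	high	3892	1	0
GUU	high	1072	0.33	0
GUC	high	9154	2.83	0
GUA	high	245	0.08	0
GUG	high	2474	0.76	0
UAU	high	531	0.2	0
UAC	high	4668	1.8	0
CAU	high	434	0.22	0
CAC	high	3436	1.78	0
CAA	high	931	0.31	0
CAG	high	4985	1.69	0
AAU	high	815	0.27	0
AAC	high	5282	1.73	0
AAA	high	885	0.2	0
AAG	high	8076	1.8	0
GAU	high	1419	0.29	0
GAC	high	8446	1.71	0
GAA	high	1498	0.33	0
GAG	high	7699	1.67	0
UCU	high	971	0.47	0
UCC	high	4120	2.01	0
UCA	high	324	0.16	0
UCG	high	3103	1.52	0
AGU	high	243	0.12	0
AGC	high	3523	1.72	0
CCU	high	939	0.41	0
CCC	high	5557	2.41	0
CCA	high	337	0.15	0
CCG	high	2409	1.04	0
ACU	high	862	0.33	0
ACC	high	5828	2.22	0
ACA	high	549	0.21	0
ACG	high	3259	1.24	0
GCU	high	2078	0.43	0
GCC	high	13066	2.69	0
GCA	high	616	0.13	0
GCG	high	3677	0.76	0
UGU	high	135	0.13	0
UGC	high	1916	1.87	0
UGG	high	2681	1	0
CGU	high	858	0.53	0
CGC	high	7293	4.5	0
CGA	high	288	0.18	0
CGG	high	756	0.47	0
AGA	high	215	0.13	0
AGG	high	312	0.19	0
GGU	high	1675	0.47	0
GGC	high	11372	3.22	0
GGA	high	486	0.14	0
GGG	high	614	0.17	0
UAA	high	299	1.73	0
UAG	high	132	0.76	0
UGA	high	87	0.5	0
UUU	low	4006	1.02	0
UUC	low	3865	0.98	0
UUA	low	1782	0.52	0
UUG	low	3947	1.14	0
CUU	low	4325	1.25	0
CUC	low	3937	1.14	0
CUA	low	2684	0.78	0
CUG	low	4053	1.17	0
AUU	low	4431	1.19	0
AUC	low	4157	1.11	0
AUA	low	2611	0.7	0
AUG	low	4860	1	0
GUU	low	3542	1.11	0
GUC	low	3887	1.21	0
GUA	low	2128	0.66	0
GUG	low	3260	1.02	0
UAU	low	2903	1.02	0
UAC	low	2809	0.98	0
CAU	low	3329	1.09	0
CAC	low	2780	0.91	0
CAA	low	5088	1.01	0
CAG	low	4946	0.99	0
AAU	low	4228	1.04	0
AAC	low	3879	0.96	0
AAA	low	4872	0.93	0
AAG	low	5585	1.07	0
GAU	low	6628	1.01	0
GAC	low	6509	0.99	0
GAA	low	6665	0.97	0
GAG	low	7095	1.03	0
UCU	low	3849	1.16	0
UCC	low	2740	0.83	0
UCA	low	3500	1.06	0
UCG	low	3056	0.92	0
AGU	low	2572	0.78	0
AGC	low	4164	1.26	0
CCU	low	3239	1.04	0
CCC	low	2302	0.74	0
CCA	low	4115	1.32	0
CCG	low	2816	0.9	0
ACU	low	3441	1.03	0
ACC	low	2873	0.86	0
ACA	low	4104	1.23	0
ACG	low	2945	0.88	0
GCU	low	5240	1.07	0
GCC	low	4782	0.97	1
GCA	low	5659	1.15	0
GCG	low	3992	0.81	0
UGU	low	1491	0.86	0
UGC	low	1971	1.14	0
UGG	low	3263	1	0
CGU	low	1920	0.77	0
CGC	low	2778	1.11	0
CGA	low	3373	1.35	0
CGG	low	1916	0.76	0
AGA	low	3024	1.21	0
AGG	low	2022	0.81	0
GGU	low	3074	0.88	0
GGC	low	4816	1.39	1
GGA	low	3678	1.06	0
GGG	low	2332	0.67	0
UAA	low	175	1.01	0
UAG	low	175	1.01	0
UGA	low	168	0.97	0
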